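"""Pseudo-time trajectory profiles and variance-sensitive fuzzy clustering.

Each metabolite's disease trajectory is summarized as an ordered 3-vector of
group means over (baseline, pre-cachectic, cachectic); the Ctrl group is the
baseline for every tissue except tumour, where Non-cax animals stand in
(control animals carry no tumour).  Profiles are z-standardized across the
three points so that only the shape of the trend matters, then sorted into
eight scenario clusters — {early, late, gradual, transient} x {up, down} —
by fuzzy c-means with cluster-specific variance weighting, validated by the
Xie-Beni index.

The variance sensitivity scales each cluster's squared distances by its
current membership-weighted dispersion (floored to avoid collapse), so tight
clusters attract only close profiles while diffuse ones tolerate spread.
Centroids are initialized at the eight canonical scenario templates and the
iteration is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import IntensityMatrix

log = logging.getLogger(__name__)

#: Canonical scenario shapes over (baseline, pre-cachectic, cachectic),
#: before z-standardization.
_TEMPLATE_SHAPES: dict[str, tuple[float, float, float]] = {
    "early-up": (0.0, 1.0, 1.0),
    "late-up": (0.0, 0.0, 1.0),
    "gradual-up": (0.0, 1.0, 2.0),
    "up-down": (0.0, 1.0, 0.0),
    "early-down": (0.0, -1.0, -1.0),
    "late-down": (0.0, 0.0, -1.0),
    "gradual-down": (0.0, -1.0, -2.0),
    "down-up": (0.0, -1.0, 0.0),
}

SCENARIO_LABELS = tuple(_TEMPLATE_SHAPES)


def zscore_profile(values: np.ndarray) -> np.ndarray:
    """Standardize a profile to mean 0, population SD 1 across its points."""
    v = np.asarray(values, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("constant profile cannot be standardized")
    return (v - v.mean()) / sd


def scenario_templates() -> np.ndarray:
    """The 8 standardized scenario centroids, in SCENARIO_LABELS order."""
    return np.vstack([zscore_profile(np.array(s)) for s in _TEMPLATE_SHAPES.values()])


@dataclass
class TrajectoryProfile:
    metabolite_id: str
    tissue: str
    values: np.ndarray  # standardized (baseline, pre-cachectic, cachectic)


@dataclass
class FuzzyClustering:
    centroids: np.ndarray            # 8 x 3
    memberships: np.ndarray          # profiles x 8
    fuzzifier: float
    xie_beni: float
    scenario_labels: tuple[str, ...] = SCENARIO_LABELS
    profile_ids: list[tuple[str, str]] = field(default_factory=list)
    n_iter: int = 0

    def hard_assignments(self) -> np.ndarray:
        return self.memberships.argmax(axis=1)


def build_profiles(matrix: IntensityMatrix, tissue: str,
                   standardize: bool = True) -> list[TrajectoryProfile]:
    """Per-metabolite pseudo-time profiles for one tissue.

    Requires groups (Ctrl | NonCax-for-tumour), PreCax and Cax; constant
    profiles are dropped with a warning because their shape is undefined.
    """
    sub = matrix.subset_tissue(tissue)
    baseline_group = "NonCax" if tissue == "tumour" else "Ctrl"
    needed = [baseline_group, "PreCax", "Cax"]
    present = sub.groups_present()
    missing = [g for g in needed if g not in present]
    if missing:
        raise ValueError(f"tissue {tissue}: required groups missing: {missing}")
    cols = {g: sub.samples_in_group(g) for g in needed}
    profiles = []
    for met in sub.metabolite_ids:
        means = np.array([sub.values.loc[met, cols[g]].mean() for g in needed])
        if standardize:
            if np.ptp(means) == 0:
                log.warning("dropping constant profile %s in %s", met, tissue)
                continue
            means = zscore_profile(means)
        profiles.append(TrajectoryProfile(met, tissue, means))
    return profiles


def _distances_sq(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - centroids[None, :, :]
    return np.einsum("ikj,ikj->ik", diff, diff)


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Standard fuzzifier-power membership update with the zero-distance
    convention: full membership shared among zero-distance clusters."""
    n, c = d2.shape
    u = np.zeros((n, c))
    zero = d2 <= 1e-300
    has_zero = zero.any(axis=1)
    if has_zero.any():
        z = zero[has_zero]
        u[has_zero] = z / z.sum(axis=1, keepdims=True)
    rest = ~has_zero
    if rest.any():
        power = 1.0 / (m - 1.0)
        ratio = (d2[rest][:, :, None] / d2[rest][:, None, :]) ** power
        u[rest] = 1.0 / ratio.sum(axis=2)
    return u


def fuzzy_cluster(profiles: list[TrajectoryProfile], fuzzifier: float = 2.0,
                  max_iter: int = 300, tol: float = 1e-6,
                  variance_sensitive: bool = True,
                  dispersion_floor: float = 1e-3) -> FuzzyClustering:
    """Cluster standardized profiles into the 8 scenario groups.

    Fuzzy c-means with c = 8, centroids initialized at the canonical
    scenario templates, cluster-specific variance weighting, and no random
    restarts — the result is deterministic for given inputs.
    """
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    x = np.vstack([p.values for p in profiles]) if profiles else np.empty((0, 3))
    c = len(SCENARIO_LABELS)
    if x.shape[0] < c:
        raise ValueError(f"need >= {c} profiles, got {x.shape[0]}")
    centroids = scenario_templates().copy()
    u = None
    scale = np.ones(c)
    it = 0
    for it in range(1, max_iter + 1):
        d2 = _distances_sq(x, centroids)
        u = _memberships(d2 / scale[None, :], fuzzifier)
        um = u ** fuzzifier
        w = um.sum(axis=0)
        new_centroids = (um.T @ x) / w[:, None]
        if variance_sensitive:
            disp = (um * d2).sum(axis=0) / w
            scale = np.maximum(disp, dispersion_floor)
        move = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if move < tol:
            break
    d2 = _distances_sq(x, centroids)
    u = _memberships(d2 / scale[None, :], fuzzifier)
    clustering = FuzzyClustering(
        centroids=centroids, memberships=u, fuzzifier=fuzzifier, xie_beni=np.nan,
        profile_ids=[(p.metabolite_id, p.tissue) for p in profiles], n_iter=it,
    )
    clustering.xie_beni = xie_beni_index(profiles, clustering)
    return clustering


def fuzzy_cluster_c(x: np.ndarray, c: int, fuzzifier: float = 2.0,
                    max_iter: int = 300, tol: float = 1e-6,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Plain fuzzy c-means with c clusters and seeded greedy farthest-point
    initialization; used for validity-index model selection over c."""
    n = x.shape[0]
    if n < c:
        raise ValueError("fewer points than clusters")
    rng = np.random.default_rng(seed)
    first = int(rng.integers(n))
    chosen = [first]
    d_min = np.linalg.norm(x - x[first], axis=1)
    for _ in range(c - 1):
        nxt = int(np.argmax(d_min))
        chosen.append(nxt)
        d_min = np.minimum(d_min, np.linalg.norm(x - x[nxt], axis=1))
    centroids = x[chosen].astype(float).copy()
    for _ in range(max_iter):
        d2 = _distances_sq(x, centroids)
        u = _memberships(d2, fuzzifier)
        um = u ** fuzzifier
        new_centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        move = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if move < tol:
            break
    u = _memberships(_distances_sq(x, centroids), fuzzifier)
    return centroids, u


def xie_beni_for_c(profiles: list[TrajectoryProfile], c_values,
                   fuzzifier: float = 2.0, seed: int = 0) -> dict[int, float]:
    """Xie-Beni index per candidate cluster count."""
    x = np.vstack([p.values for p in profiles])
    out = {}
    for c in c_values:
        v, u = fuzzy_cluster_c(x, c, fuzzifier=fuzzifier, seed=seed)
        d2 = _distances_sq(x, v)
        numer = ((u ** fuzzifier) * d2).sum()
        sep = _distances_sq(v, v)
        np.fill_diagonal(sep, np.inf)
        out[c] = float(numer / (x.shape[0] * sep.min()))
    return out


def xie_beni_index(profiles: list[TrajectoryProfile],
                   clustering: FuzzyClustering) -> float:
    """XB = sum_k sum_i u_ik^m ||x_i - v_k||^2 / (n * min_{j!=l} ||v_j - v_l||^2).

    Lower is better.  Coincident centroids make the index undefined.
    """
    x = np.vstack([p.values for p in profiles])
    v = clustering.centroids
    u = clustering.memberships
    d2 = _distances_sq(x, v)
    numer = ((u ** clustering.fuzzifier) * d2).sum()
    sep = _distances_sq(v, v)
    np.fill_diagonal(sep, np.inf)
    min_sep = sep.min()
    if min_sep <= 1e-12:
        raise ValueError("degenerate clustering: coincident centroids")
    return float(numer / (x.shape[0] * min_sep))


def rank_members(clustering: FuzzyClustering, top_n: int = 10) -> pd.DataFrame:
    """Top members per cluster by membership, ties broken lexicographically."""
    rows = []
    assign = clustering.hard_assignments()
    for k, label in enumerate(clustering.scenario_labels):
        idx = np.where(assign == k)[0]
        ranked = sorted(idx, key=lambda i: (-clustering.memberships[i, k],
                                            clustering.profile_ids[i]))
        for rank, i in enumerate(ranked[:top_n], start=1):
            met, tissue = clustering.profile_ids[i]
            rows.append((label, rank, met, tissue,
                         float(clustering.memberships[i, k])))
    return pd.DataFrame(rows, columns=["cluster", "rank", "metabolite_id",
                                       "tissue", "membership"])


def contribution_tables(
    clustering: FuzzyClustering,
    metabolite_classes: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sankey-style contingency tables: tissue x cluster and cluster x class.

    Each profile is hard-assigned to its maximal-membership cluster; grand
    totals equal the number of profiles.
    """
    assign = clustering.hard_assignments()
    labels = clustering.scenario_labels
    tissue_rows = []
    class_rows = []
    for i, (met, tissue) in enumerate(clustering.profile_ids):
        cluster = labels[assign[i]]
        tissue_rows.append((tissue, cluster))
        cls = (metabolite_classes or {}).get(met, "other")
        class_rows.append((cluster, cls))
    tissue_tab = (pd.DataFrame(tissue_rows, columns=["tissue", "cluster"])
                  .value_counts().unstack(fill_value=0).sort_index())
    class_tab = (pd.DataFrame(class_rows, columns=["cluster", "cls"])
                 .value_counts().unstack(fill_value=0).sort_index())
    return tissue_tab, class_tab
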