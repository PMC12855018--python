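"""Per-tissue differential metabolite analysis and the cross-tissue
cachexia signature.

Each metabolite is tested by classical one-way ANOVA across the four
experimental groups, followed by Tukey's honestly-significant-difference
procedure for all pairwise contrasts (Tukey-Kramer form for unbalanced
groups).  No across-metabolite multiplicity correction is applied: Tukey
corrects across contrasts only, and significance is reported at the
per-metabolite level.

The cross-tissue signature collects metabolites that move consistently in
cachexia: a metabolite joins the up (down) signature iff, in at least two
cachexia target tissues (tumour excluded), both the Cax-Ctrl and the
Cax-NonCax contrasts are significant with positive (negative) mean
differences in both contrasts in those same tissues.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import CACHEXIA_TARGET_TISSUES
from .datatypes import IntensityMatrix

log = logging.getLogger(__name__)


@dataclass
class DifferentialResult:
    """ANOVA + Tukey results for one metabolite in one tissue."""

    tissue: str
    metabolite_id: str
    f_stat: float
    p_anova: float
    contrasts: dict[tuple[str, str], tuple[float, float]]
    log2fc_cax_ctrl: float = np.nan
    log2fc_cax_noncax: float = np.nan
    degenerate: bool = False


def anova_oneway(values_by_group: dict[str, np.ndarray]) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA F statistic and p-value."""
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("anova_oneway needs >= 2 groups with >= 2 observations")
    if all(np.ptp(g) == 0 for g in groups):
        means = [g.mean() for g in groups]
        if np.ptp(means) > 0:
            # zero within-group variance with unequal means: boundary case
            return np.inf, 0.0
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def tukey_hsd(values_by_group: dict[str, np.ndarray]
              ) -> dict[tuple[str, str], tuple[float, float]]:
    """All-pairs Tukey HSD: mean differences and studentized-range p-values.

    Returned keys are ordered pairs in both directions with antisymmetric
    differences and identical p-values.
    """
    names = list(values_by_group)
    groups = [np.asarray(values_by_group[n], dtype=float) for n in names]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("tukey_hsd needs >= 2 groups with >= 2 observations")
    res = stats.tukey_hsd(*groups)
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for i, j in itertools.combinations(range(len(names)), 2):
        diff = float(groups[i].mean() - groups[j].mean())
        p = float(res.pvalue[i, j])
        out[(names[i], names[j])] = (diff, p)
        out[(names[j], names[i])] = (-diff, p)
    return out


def log2_fold_change(matrix: IntensityMatrix, numerator_group: str,
                     denominator_group: str, tissue: str | None = None,
                     log_base: str = "natural") -> pd.Series:
    """Per-metabolite log2 fold change between two group means.

    The matrix is log-scale; the difference of means is converted from the
    matrix's log base into base-2 units.
    """
    if matrix.scale != "log":
        raise ValueError("log2_fold_change expects a log-scale matrix")
    num_cols = matrix.samples_in_group(numerator_group, tissue)
    den_cols = matrix.samples_in_group(denominator_group, tissue)
    if not num_cols or not den_cols:
        raise ValueError("both groups must be present")
    diff = matrix.values[num_cols].mean(axis=1) - matrix.values[den_cols].mean(axis=1)
    factor = {"natural": 1.0 / np.log(2), "2": 1.0, "10": np.log2(10)}[log_base]
    return diff * factor


def differential_tissue(matrix: IntensityMatrix, tissue: str,
                        log_base: str = "natural") -> list[DifferentialResult]:
    """ANOVA + Tukey for every metabolite of one tissue's processed matrix."""
    sub = matrix.subset_tissue(tissue)
    groups = sub.groups_present()
    cols_by_group = {g: sub.samples_in_group(g) for g in groups}
    results = []
    fc_ctrl = (log2_fold_change(sub, "Cax", "Ctrl", log_base=log_base)
               if "Ctrl" in groups and "Cax" in groups else None)
    fc_nc = (log2_fold_change(sub, "Cax", "NonCax", log_base=log_base)
             if "NonCax" in groups and "Cax" in groups else None)
    for met in sub.metabolite_ids:
        vbg = {g: sub.values.loc[met, cols].to_numpy(dtype=float)
               for g, cols in cols_by_group.items()}
        if any(len(v) < 2 for v in vbg.values()):
            log.warning("skipping %s in %s: a group has < 2 observations",
                        met, tissue)
            continue
        degenerate = all(np.ptp(v) == 0 for v in vbg.values())
        f, p = anova_oneway(vbg)
        contrasts = (tukey_hsd(vbg) if not degenerate
                     else {pair: (float(vbg[pair[0]].mean() - vbg[pair[1]].mean()),
                                  0.0 if f > 0 else 1.0)
                           for pair in itertools.permutations(vbg, 2)})
        results.append(DifferentialResult(
            tissue=tissue, metabolite_id=met, f_stat=f, p_anova=p,
            contrasts=contrasts,
            log2fc_cax_ctrl=float(fc_ctrl[met]) if fc_ctrl is not None else np.nan,
            log2fc_cax_noncax=float(fc_nc[met]) if fc_nc is not None else np.nan,
            degenerate=degenerate,
        ))
    return results


@dataclass
class SignatureSet:
    """Cross-tissue signature: metabolites consistently up or down in
    cachexia in at least two target tissues."""

    direction: str
    members: list[tuple[str, list[str]]] = field(default_factory=list)


def cross_tissue_signature(
    results: list[DifferentialResult],
    alpha: float = 0.05,
    min_tissues: int = 2,
    require_direction_agreement: bool = True,
) -> tuple[SignatureSet, SignatureSet]:
    """Extract the up- and down-regulated cross-tissue cachexia signatures.

    A tissue supports a metabolite in a given direction iff both the
    Cax-Ctrl and Cax-NonCax Tukey contrasts have p < alpha and (when
    direction agreement is required) mean differences of the matching sign
    in both contrasts.  Tumour results are excluded with a warning.
    """
    by_met: dict[str, dict[str, DifferentialResult]] = {}
    for r in results:
        if r.tissue == "tumour":
            log.warning("tumour results excluded from the cross-tissue signature")
            continue
        if r.tissue not in CACHEXIA_TARGET_TISSUES:
            raise ValueError(f"unknown tissue {r.tissue!r}")
        by_met.setdefault(r.metabolite_id, {})[r.tissue] = r

    up = SignatureSet("up")
    down = SignatureSet("down")
    for met in sorted(by_met):
        support = {"up": [], "down": []}
        for tissue in CACHEXIA_TARGET_TISSUES:
            r = by_met[met].get(tissue)
            if r is None:
                continue
            c1 = r.contrasts.get(("Cax", "Ctrl"))
            c2 = r.contrasts.get(("Cax", "NonCax"))
            if c1 is None or c2 is None:
                continue
            (d1, p1), (d2, p2) = c1, c2
            if p1 >= alpha or p2 >= alpha:
                continue
            if require_direction_agreement:
                if d1 > 0 and d2 > 0:
                    support["up"].append(tissue)
                elif d1 < 0 and d2 < 0:
                    support["down"].append(tissue)
            else:
                support["up" if d1 > 0 else "down"].append(tissue)
        if len(support["up"]) >= min_tissues:
            up.members.append((met, support["up"]))
        if len(support["down"]) >= min_tissues:
            down.members.append((met, support["down"]))
    return up, down


def results_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    """Long CSV-ready table of all contrasts."""
    rows = []
    for r in results:
        seen = set()
        for (a, b), (diff, p) in sorted(r.contrasts.items()):
            if frozenset((a, b)) in seen:
                continue
            seen.add(frozenset((a, b)))
            rows.append((r.tissue, r.metabolite_id, r.f_stat, r.p_anova,
                         a, b, diff, p, r.log2fc_cax_ctrl, r.log2fc_cax_noncax,
                         r.degenerate))
    return pd.DataFrame(rows, columns=[
        "tissue", "metabolite_id", "f_stat", "p_anova", "group_a", "group_b",
        "mean_diff", "p_tukey", "log2fc_cax_ctrl", "log2fc_cax_noncax",
        "degenerate"])
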