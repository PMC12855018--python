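"""Per-tissue preprocessing chain for metabolite intensity matrices.

Order of operations: log transform -> outlier masking (mean + 4*SD) ->
missingness filter (> 25% missing removed) -> RSD filter (above the 80th
percentile in any condition removed) -> knn imputation.  All thresholds are
parameters with these defaults.

The outlier rule operates per metabolite across all samples of a tissue on
the log scale, in a single pass with a strictly-greater comparison.
"Condition" for the missingness and RSD filters is the experimental group
within the tissue.  The RSD is computed on raw-scale values, since the
coefficient of variation of log-transformed values is not scale-free; the
raw matrix is carried alongside the log matrix for this purpose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

from .constants import PERCENTILE_METHOD
from .datatypes import IntensityMatrix

_LOG_FN = {"natural": np.log, "2": np.log2, "10": np.log10}


@dataclass
class PreprocessParams:
    """Thresholds of the preprocessing chain (defaults as published)."""

    outlier_sd_multiplier: float = 4.0
    missing_fraction_max: float = 0.25
    rsd_percentile: float = 80.0
    knn_k: int = 5
    log_base: str = "natural"

    def __post_init__(self) -> None:
        if self.outlier_sd_multiplier <= 0:
            raise ValueError("outlier_sd_multiplier must be positive")
        if not 0.0 <= self.missing_fraction_max < 1.0:
            raise ValueError("missing_fraction_max must be in [0, 1)")
        if not 0.0 < self.rsd_percentile <= 100.0:
            raise ValueError("rsd_percentile must be in (0, 100]")
        if self.knn_k < 1:
            raise ValueError("knn_k must be a positive integer")
        if self.log_base not in _LOG_FN:
            raise ValueError(f"log_base must be one of {sorted(_LOG_FN)}")


@dataclass
class PreprocessReport:
    """Tallies of one preprocessing run; the identity
    n_input - n_removed_missingness - n_removed_rsd == len(retained_ids)
    always holds."""

    n_input: int = 0
    n_outlier_cells_masked: int = 0
    n_removed_missingness: int = 0
    n_removed_rsd: int = 0
    n_imputed_cells: int = 0
    n_fallback_imputed: int = 0
    retained_ids: list[str] = field(default_factory=list)

    def check(self) -> None:
        if self.n_input - self.n_removed_missingness - self.n_removed_rsd != len(
            self.retained_ids
        ):
            raise AssertionError("preprocess report tallies are inconsistent")


def log_transform(matrix: IntensityMatrix, base: str = "natural") -> IntensityMatrix:
    """Log-transform a raw matrix; missing cells stay missing.

    Zero or negative observed values are a hard error — no silent
    pseudo-count is applied.
    """
    if matrix.scale != "raw":
        raise ValueError("log_transform expects a raw-scale matrix")
    vals = matrix.values
    bad = (vals <= 0) & vals.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-positive intensity at ({vals.index[r]}, {vals.columns[c]}); "
            "cannot log-transform"
        )
    out = matrix.with_values(_LOG_FN[base](vals), scale="log")
    out.raw_values = vals.copy()
    return out


def mask_outliers(
    matrix: IntensityMatrix, multiplier: float = 4.0
) -> tuple[IntensityMatrix, set[tuple[str, str]]]:
    """Mask cells strictly greater than the per-metabolite mean + multiplier*SD.

    Mean and SD are computed over the observed values of each metabolite
    across all samples of the tissue, in one pass (no iteration).  A
    metabolite with <= 1 observed value, or with zero SD, masks nothing.
    """
    if matrix.scale != "log":
        raise ValueError("mask_outliers expects a log-scale matrix")
    vals = matrix.values
    mean = vals.mean(axis=1, skipna=True)
    sd = vals.std(axis=1, ddof=1, skipna=True)
    threshold = mean + multiplier * sd
    exceed = vals.gt(threshold, axis=0)
    masked = {
        (vals.index[r], vals.columns[c])
        for r, c in np.argwhere(exceed.to_numpy())
    }
    out_vals = vals.mask(exceed)
    out = matrix.with_values(out_vals)
    return out, masked


def filter_missingness(
    matrix: IntensityMatrix, max_fraction: float = 0.25
) -> tuple[IntensityMatrix, list[str]]:
    """Remove metabolites whose missing fraction across all samples is
    strictly greater than ``max_fraction`` (exactly at the bound is kept)."""
    frac = matrix.values.isna().mean(axis=1)
    removed = list(frac.index[frac > max_fraction])
    kept = [m for m in matrix.metabolite_ids if m not in set(removed)]
    return matrix.subset_metabolites(kept), removed


def _per_condition_rsd(matrix: IntensityMatrix) -> pd.DataFrame:
    """RSD (sd/mean of observed raw-scale values) per metabolite per group.

    A (metabolite, group) cell with fewer than 2 observed values contributes
    no RSD (NaN).
    """
    raw = matrix.raw_values
    if raw is None:
        if matrix.scale == "raw":
            raw = matrix.values
        else:
            raise ValueError("RSD filter needs raw-scale values alongside the "
                             "log matrix")
    raw = raw.loc[matrix.metabolite_ids]
    # respect outlier masking done on the log matrix
    raw = raw.mask(matrix.values.isna()) if matrix.scale == "log" else raw
    cols_by_group = {}
    for s in matrix.samples:
        cols_by_group.setdefault(s.group, []).append(s.sample_id)
    out = {}
    for group, cols in cols_by_group.items():
        sub = raw[cols]
        n_obs = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1, skipna=True)
        sd = sub.std(axis=1, ddof=1, skipna=True)
        rsd = sd / mean
        rsd[n_obs < 2] = np.nan
        out[group] = rsd
    return pd.DataFrame(out)


def filter_rsd(
    matrix: IntensityMatrix, percentile: float = 80.0
) -> tuple[IntensityMatrix, list[str]]:
    """Remove metabolites whose RSD strictly exceeds the given percentile of
    the per-condition RSD distribution in at least one condition.

    The percentile is computed across metabolites within each condition,
    with linear interpolation between order statistics.
    """
    rsd = _per_condition_rsd(matrix)
    removed: set[str] = set()
    for group in rsd.columns:
        col = rsd[group].dropna()
        if col.empty:
            continue
        cut = np.percentile(col.to_numpy(), percentile, method=PERCENTILE_METHOD)
        removed.update(col.index[col > cut])
    kept = [m for m in matrix.metabolite_ids if m not in removed]
    return matrix.subset_metabolites(kept), sorted(removed)


def knn_impute(
    matrix: IntensityMatrix, k: int = 5
) -> tuple[IntensityMatrix, set[tuple[str, str]], int]:
    """Impute missing cells from the k nearest metabolite profiles.

    Distances are Euclidean over mutually observed samples, rescaled by the
    number of shared samples (the NaN-Euclidean convention).  Donors must be
    observed in the target sample; each donates equally (unweighted mean).
    A cell with no eligible donor falls back to the metabolite's own
    observed mean; the count of such cells is returned.
    """
    vals = matrix.values.to_numpy(dtype=float).copy()
    n_met = vals.shape[0]
    missing = np.argwhere(np.isnan(vals))
    if missing.size == 0:
        return matrix, set(), 0
    if np.isnan(vals).all(axis=1).any():
        raise ValueError("a metabolite with no observed values cannot be imputed")
    dist = nan_euclidean_distances(vals, vals)
    np.fill_diagonal(dist, np.inf)
    imputed_cells: set[tuple[str, str]] = set()
    n_fallback = 0
    out = vals.copy()
    for r, c in missing:
        donors = np.where(~np.isnan(vals[:, c]))[0]
        donors = donors[donors != r]
        d = dist[r, donors]
        donors = donors[~np.isnan(d)]
        d = d[~np.isnan(d)]
        if donors.size == 0:
            out[r, c] = np.nanmean(vals[r])
            n_fallback += 1
        else:
            order = np.argsort(d, kind="stable")[:k]
            out[r, c] = vals[donors[order], c].mean()
        imputed_cells.add((matrix.metabolite_ids[r], matrix.sample_ids[c]))
    frame = pd.DataFrame(out, index=matrix.values.index,
                         columns=matrix.values.columns)
    return matrix.with_values(frame), imputed_cells, n_fallback


def run_preprocess(
    matrix: IntensityMatrix, params: PreprocessParams | None = None
) -> tuple[IntensityMatrix, PreprocessReport]:
    """Run the five-stage chain on one tissue's raw matrix."""
    params = params or PreprocessParams()
    tissues = {s.tissue for s in matrix.samples}
    if len(tissues) != 1:
        raise ValueError("run_preprocess expects a single-tissue matrix; "
                         f"got tissues {sorted(tissues)}")
    report = PreprocessReport(n_input=len(matrix.metabolites))
    logged = log_transform(matrix, params.log_base)
    masked_m, cells = mask_outliers(logged, params.outlier_sd_multiplier)
    report.n_outlier_cells_masked = len(cells)
    filt1, removed_miss = filter_missingness(masked_m, params.missing_fraction_max)
    report.n_removed_missingness = len(removed_miss)
    filt2, removed_rsd = filter_rsd(filt1, params.rsd_percentile)
    report.n_removed_rsd = len(removed_rsd)
    imputed, imp_cells, n_fb = knn_impute(filt2, params.knn_k)
    report.n_imputed_cells = len(imp_cells)
    report.n_fallback_imputed = n_fb
    report.retained_ids = list(imputed.metabolite_ids)
    report.check()
    return imputed, report
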