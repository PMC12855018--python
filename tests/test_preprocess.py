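"""Preprocessing chain: log transform, outlier mask, filters, imputation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from m3cax.preprocess import (
    PreprocessParams,
    filter_missingness,
    filter_rsd,
    knn_impute,
    log_transform,
    mask_outliers,
    run_preprocess,
)
from m3cax.synthetic import build_toy_fixture


def test_log_transform_basic(matrix_factory):
    m = matrix_factory(np.full((2, 8), 1.0), groups=("Ctrl", "Cax"))
    out = log_transform(m)
    assert (out.values.to_numpy() == 0).all()
    assert out.scale == "log"

    m2 = matrix_factory(np.full((1, 8), np.e), groups=("Ctrl", "Cax"))
    np.testing.assert_allclose(log_transform(m2).values.to_numpy(), 1.0)


def test_log_transform_preserves_missing_and_rejects_zero(matrix_factory):
    vals = np.full((2, 8), 2.0)
    vals[0, 3] = np.nan
    m = matrix_factory(vals, groups=("Ctrl", "Cax"))
    out = log_transform(m)
    assert np.isnan(out.values.iloc[0, 3])
    assert out.values.isna().sum().sum() == 1

    vals[1, 0] = 0.0
    m0 = matrix_factory(vals, groups=("Ctrl", "Cax"))
    with pytest.raises(ValueError, match="M002"):
        log_transform(m0)


def test_mask_outliers_constant_vector_masks_nothing(matrix_factory):
    m = log_transform(matrix_factory(np.full((3, 16), 5.0)))
    out, masked = mask_outliers(m, 4.0)
    assert masked == set()


def test_mask_outliers_spike_follows_full_vector_rule(matrix_factory):
    rng = np.random.default_rng(5)
    base = rng.normal(10, 0.5, size=16)
    # inject a spike at mean + 10*sd of the REMAINING values
    spike_val = base[:15].mean() + 10 * base[:15].std(ddof=1)
    vals = base.copy()
    vals[15] = spike_val
    m = matrix_factory(np.exp(vals[None, :]))
    out, masked = mask_outliers(log_transform(m), 4.0)
    # oracle: strictly-greater comparison against full-vector mean + 4*sd
    thresh = vals.mean() + 4 * vals.std(ddof=1)
    expected = {("M001", m.sample_ids[15])} if spike_val > thresh else set()
    assert masked == expected
    # a huge multiplier masks nothing
    _, none_masked = mask_outliers(log_transform(m), 1e6)
    assert none_masked == set()


def test_missingness_boundary_kept_at_exactly_25_percent():
    m = log_transform(build_toy_fixture("missingness_boundary"))
    filtered, removed = filter_missingness(m, 0.25)
    assert "M1" in filtered.metabolite_ids      # 4/16 = 25% exactly: kept
    assert removed == ["M2"]                    # 5/16: removed
    # no missing anywhere -> nothing removed
    clean = filtered.subset_metabolites(
        [i for i in filtered.metabolite_ids if i != "M1"])
    _, removed2 = filter_missingness(clean, 0.25)
    assert removed2 == []


def test_rsd_ladder_cut_sits_at_stated_percentile():
    m = build_toy_fixture("rsd_ladder")
    filtered, removed = filter_rsd(m, 80.0)
    # oracle: direct percentile computation under the linear-interpolation
    # convention on the 10 Ctrl RSDs
    ctrl = m.values.iloc[:, :4]
    rsd = (ctrl.std(axis=1, ddof=1) / ctrl.mean(axis=1)).to_numpy()
    cut = np.percentile(rsd, 80.0)
    expected_removed = sorted(np.array(m.metabolite_ids)[rsd > cut])
    assert removed == expected_removed
    assert len(removed) == 2
    # the retained maximum has percentile rank 80 among the RSD ladder
    retained_max = max(rsd[rsd <= cut])
    assert stats.percentileofscore(rsd, retained_max, kind="weak") == 80.0


def test_rsd_identical_values_and_percentile_100(matrix_factory):
    vals = np.tile(np.array([10.0, 12, 14, 16] * 4), (5, 1))
    m = matrix_factory(vals)
    _, removed = filter_rsd(m, 80.0)
    assert removed == []  # identical RSDs: none strictly exceeds
    ladder = build_toy_fixture("rsd_ladder")
    _, removed100 = filter_rsd(ladder, 100.0)
    assert removed100 == []


def test_knn_impute_contracts(matrix_factory):
    vals = np.arange(32, dtype=float).reshape(2, 16)
    m = log_transform(matrix_factory(np.exp(vals)))
    out, cells, n_fb = knn_impute(m, 3)
    assert cells == set() and n_fb == 0
    pd.testing.assert_frame_equal(out.values, m.values)

    # k=1 with a duplicate profile differing only at the missing cell
    vals = np.vstack([np.arange(16.0), np.arange(16.0), 5 + np.arange(16.0)])
    vals[0, 7] = np.nan
    df = pd.DataFrame(np.exp(vals))
    m2 = log_transform(matrix_factory(np.exp(vals)))
    out2, cells2, _ = knn_impute(m2, 1)
    assert out2.values.iloc[0, 7] == pytest.approx(7.0)
    assert cells2 == {("M001", m2.sample_ids[7])}


def test_knn_beats_column_mean_imputation(matrix_factory):
    rng = np.random.default_rng(17)
    n_met, n_s = 40, 16
    profiles = rng.normal(0, 1, size=(8, n_s))
    truth = profiles[rng.integers(0, 8, n_met)] + rng.normal(
        10, 0.5, size=(n_met, 1)) + rng.normal(0, 0.1, size=(n_met, n_s))
    masked = truth.copy()
    holes = [(r, c) for r, c in zip(rng.integers(0, n_met, 30),
                                    rng.integers(0, n_s, 30))]
    for r, c in holes:
        masked[r, c] = np.nan
    m = matrix_factory(np.exp(masked))
    m.scale = "log"
    m.values[:] = masked
    out, _, _ = knn_impute(m, 5)
    knn_mse = np.mean([(out.values.iloc[r, c] - truth[r, c]) ** 2
                       for r, c in holes])
    col_mean = np.nanmean(masked, axis=0)
    mean_mse = np.mean([(col_mean[c] - truth[r, c]) ** 2 for r, c in holes])
    assert knn_mse < mean_mse


def test_filters_are_idempotent_and_monotone():
    m = log_transform(build_toy_fixture("missingness_boundary"))
    once, removed1 = filter_missingness(m, 0.25)
    twice, removed2 = filter_missingness(once, 0.25)
    assert removed2 == []
    pd.testing.assert_frame_equal(once.values, twice.values)
    # raising the threshold never removes more
    _, removed_low = filter_missingness(m, 0.20)
    _, removed_high = filter_missingness(m, 0.40)
    assert set(removed_high) <= set(removed_low)

    ladder = build_toy_fixture("rsd_ladder")
    _, r80 = filter_rsd(ladder, 80.0)
    _, r90 = filter_rsd(ladder, 90.0)
    assert set(r90) <= set(r80)


def test_rsd_filter_idempotent_only_on_flat_distributions(matrix_factory):
    """A percentile threshold recomputed on the survivors keeps biting:
    re-application removes more of the ladder, whereas a flat RSD
    distribution is a fixed point (nothing strictly exceeds its own
    percentile)."""
    ladder = build_toy_fixture("rsd_ladder")
    f80, first = filter_rsd(ladder, 80.0)
    _, again = filter_rsd(f80, 80.0)
    assert len(first) == 2 and len(again) > 0  # not idempotent by design
    vals = np.tile(np.array([10.0, 12, 14, 16] * 4), (6, 1))
    flat = matrix_factory(vals)
    once, _ = filter_rsd(flat, 80.0)
    _, removed = filter_rsd(once, 80.0)
    assert removed == []


def test_run_preprocess_clean_fixture_and_report_identity(matrix_factory):
    rng = np.random.default_rng(23)
    vals = np.exp(rng.normal(10, 0.1, size=(12, 16)))
    m = matrix_factory(vals)
    out, report = run_preprocess(m, PreprocessParams())
    assert report.n_outlier_cells_masked == 0
    assert report.n_removed_missingness == 0
    assert report.n_imputed_cells == 0
    report.check()
    # determinism
    out2, report2 = run_preprocess(m, PreprocessParams())
    pd.testing.assert_frame_equal(out.values, out2.values)
    assert report.retained_ids == report2.retained_ids


def test_run_preprocess_missingness_boundary_fixture():
    m = build_toy_fixture("missingness_boundary")
    out, report = run_preprocess(m, PreprocessParams())
    assert "M2" not in report.retained_ids
    assert "M1" in set(report.retained_ids) | set()  # kept at exactly 25%
    assert report.n_removed_missingness == 1
    assert not out.values.isna().to_numpy().any()
    report.check()


def test_null_survival_matches_analytic_expectation():
    """Filtering calibration on null synthetic data.

    A percentile-based RSD cut removes ~20% of metabolites per condition by
    construction; over 4 near-independent conditions the expected survival
    is about 0.8^4 ~ 41%.  The missingness filter at the default 5% missing
    rate removes almost nothing (P[Binom(16, 0.05) > 4] ~ 0.002).
    """
    from m3cax.synthetic import CohortConfig, generate_cohort

    cfg = CohortConfig(n_tissues=1, n_metabolites=200, seed=99,
                       outlier_rate=0.0, template_weights={"null": 1.0})
    matrix, truth = generate_cohort(cfg)
    out, report = run_preprocess(matrix.subset_tissue("plasma"),
                                 PreprocessParams())
    assert report.n_removed_missingness <= 5
    survival = len(report.retained_ids) / 200
    assert 0.30 <= survival <= 0.52
    report.check()
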