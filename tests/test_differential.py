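"""One-way ANOVA, Tukey HSD and the cross-tissue cachexia signature."""

import numpy as np
import pytest
from scipy import stats

from m3cax.differential import (
    DifferentialResult,
    anova_oneway,
    cross_tissue_signature,
    differential_tissue,
    log2_fold_change,
    tukey_hsd,
)
from m3cax.preprocess import log_transform
from m3cax.synthetic import build_toy_fixture


def _groups_from_matrix(matrix, met):
    m = log_transform(matrix)
    return {g: m.values.loc[met, m.samples_in_group(g)].to_numpy()
            for g in m.groups_present()}


def test_anova_equal_means_gives_f0_p1():
    g = {"a": np.array([1.0, 2, 3]), "b": np.array([0.0, 2, 4]),
         "c": np.array([2.0, 2, 2])}
    f, p = anova_oneway(g)
    assert f == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_anova_two_groups_equals_t_squared():
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
    f, p_f = anova_oneway({"a": a, "b": b})
    t, p_t = stats.ttest_ind(a, b)
    assert f == pytest.approx(t ** 2)
    assert p_f == pytest.approx(p_t)


def test_anova_zero_variance_boundary():
    f, p = anova_oneway({"a": np.array([1.0, 1.0]), "b": np.array([2.0, 2.0])})
    assert np.isinf(f) and p == 0.0
    with pytest.raises(ValueError):
        anova_oneway({"a": np.array([1.0])})


def test_tukey_shift_fixture_agrees_with_permutation_oracle():
    """The shifted metabolite is significant; the ANOVA p agrees with a
    label-permutation oracle within Monte-Carlo error."""
    matrix = build_toy_fixture("tukey_shift")
    vbg = _groups_from_matrix(matrix, "M01")
    f_obs, p = anova_oneway(vbg)
    assert p < 0.05

    # permutation oracle on an unshifted metabolite (moderate p so that the
    # Monte-Carlo comparison is informative)
    vbg2 = _groups_from_matrix(matrix, "M02")
    f2, p2 = anova_oneway(vbg2)
    pooled = np.concatenate(list(vbg2.values()))
    sizes = [len(v) for v in vbg2.values()]
    rng = np.random.default_rng(11)
    n_perm, hits = 10_000, 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        f_p, _ = stats.f_oneway(*parts)
        hits += f_p >= f2
    p_perm = hits / n_perm
    assert p2 == pytest.approx(p_perm, abs=4 * np.sqrt(p_perm * (1 - p_perm)
                                                       / n_perm) + 0.01)


def test_tukey_pairs_and_monte_carlo_oracle():
    """Tukey p-values: identical groups ~1, shifted group < 0.05,
    antisymmetric differences, and agreement with a Monte-Carlo
    studentized-range oracle."""
    matrix = build_toy_fixture("tukey_shift")
    vbg = _groups_from_matrix(matrix, "M01")
    res = tukey_hsd(vbg)
    # two unshifted groups: p ~ 1
    assert res[("Ctrl", "NonCax")][1] > 0.9
    # the shifted Cax group vs any other: p < 0.05
    for other in ("Ctrl", "NonCax", "PreCax"):
        assert res[("Cax", other)][1] < 0.05
        d_ab, _ = res[("Cax", other)]
        d_ba, _ = res[(other, "Cax")]
        assert d_ab == pytest.approx(-d_ba)

    # Monte-Carlo studentized-range oracle for one balanced contrast
    vbg2 = _groups_from_matrix(matrix, "M03")
    res2 = tukey_hsd(vbg2)
    k, n = 4, 4
    groups = list(vbg2.values())
    mse = np.mean([np.var(g, ddof=1) for g in groups])
    pair = ("Ctrl", "Cax")
    q_obs = abs(res2[pair][0]) / np.sqrt(mse / n)
    rng = np.random.default_rng(7)
    sims = rng.normal(size=(20_000, k, n))
    means = sims.mean(axis=2)
    mse_sim = sims.var(axis=2, ddof=1).mean(axis=1)
    q_null = (means.max(axis=1) - means.min(axis=1)) / np.sqrt(mse_sim / n)
    p_mc = float((q_null >= q_obs).mean())
    p_tukey = res2[pair][1]
    mc_se = np.sqrt(p_mc * (1 - p_mc) / 20_000)
    assert p_tukey == pytest.approx(p_mc, abs=4 * mc_se + 0.01)


def test_tukey_p_at_least_unadjusted_pairwise_p():
    rng = np.random.default_rng(19)
    vbg = {g: rng.normal(i * 0.5, 1, 5) for i, g in
           enumerate(["Ctrl", "NonCax", "PreCax", "Cax"])}
    res = tukey_hsd(vbg)
    names = list(vbg)
    df_w = sum(len(v) for v in vbg.values()) - len(vbg)
    mse = (sum(np.var(v, ddof=1) * (len(v) - 1) for v in vbg.values()) / df_w)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt(mse * (1 / len(vbg[a]) + 1 / len(vbg[b])))
            t_stat = abs(vbg[a].mean() - vbg[b].mean()) / se
            p_unadj = 2 * stats.t.sf(t_stat, df_w)
            assert res[(a, b)][1] >= p_unadj - 1e-12


def test_log2_fold_change_units_and_sign(matrix_factory):
    vals = np.exp(np.column_stack([np.full((3, 8), 1.0),
                                   np.full((3, 8), 1.0 + np.log(2))]))
    m = log_transform(matrix_factory(vals, groups=("Ctrl", "Cax"), n_rep=8))
    fc = log2_fold_change(m, "Cax", "Ctrl")
    np.testing.assert_allclose(fc, 1.0)
    fc_rev = log2_fold_change(m, "Ctrl", "Cax")
    np.testing.assert_allclose(fc_rev, -1.0)
    equal = log2_fold_change(m, "Ctrl", "Ctrl")
    np.testing.assert_allclose(equal, 0.0)


def _result(tissue, met, d1, p1, d2, p2):
    return DifferentialResult(
        tissue=tissue, metabolite_id=met, f_stat=1.0, p_anova=0.01,
        contrasts={("Cax", "Ctrl"): (d1, p1), ("Cax", "NonCax"): (d2, p2)})


def test_signature_rule_forced_cases():
    results = [
        # up in liver and eWAT vs both controls -> member
        _result("liver", "A", 1.0, 0.01, 0.8, 0.02),
        _result("eWAT", "A", 0.9, 0.03, 0.7, 0.01),
        # significant in liver only -> excluded
        _result("liver", "B", 1.0, 0.01, 0.8, 0.02),
        _result("eWAT", "B", 0.9, 0.50, 0.7, 0.50),
        # up vs Ctrl but p = 0.2 vs NonCax everywhere -> excluded
        _result("liver", "C", 1.0, 0.01, 0.8, 0.20),
        _result("eWAT", "C", 0.9, 0.01, 0.7, 0.20),
        # down in two tissues -> down member
        _result("heart", "D", -1.0, 0.01, -0.5, 0.02),
        _result("soleus", "D", -0.8, 0.01, -0.6, 0.01),
        # discordant directions -> excluded
        _result("liver", "E", 1.0, 0.01, -0.8, 0.02),
        _result("eWAT", "E", 1.0, 0.01, -0.8, 0.02),
    ]
    up, down = cross_tissue_signature(results)
    assert [(m, sorted(t)) for m, t in up.members] == [("A", ["eWAT", "liver"])]
    assert [m for m, _ in down.members] == ["D"]

    # invariance to input order
    up2, down2 = cross_tissue_signature(list(reversed(results)))
    assert up.members == up2.members and down.members == down2.members


def test_signature_excludes_tumour_with_warning(caplog):
    results = [_result("liver", "A", 1.0, 0.01, 0.8, 0.02),
               _result("eWAT", "A", 0.9, 0.03, 0.7, 0.01),
               _result("tumour", "A", 5.0, 0.001, 5.0, 0.001)]
    up, _ = cross_tissue_signature(results)
    assert up.members[0][1] == ["liver", "eWAT"] or \
        sorted(up.members[0][1]) == ["eWAT", "liver"]
    assert "tumour" not in up.members[0][1]


def test_type_i_error_calibrated_under_null():
    """Fraction of null metabolites with p < 0.05 stays within binomial
    99% bounds of 0.05 (n = 2000)."""
    rng = np.random.default_rng(42)
    n_met = 2000
    data = rng.normal(size=(4, n_met, 4))  # 4 groups x mets x replicates
    f, p = stats.f_oneway(*[data[i].T for i in range(4)], axis=0)
    frac = (p < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / n_met)
    assert abs(frac - 0.05) < 2.58 * se + 1e-9


def test_planted_signature_recall_and_false_inclusion():
    """Cross-tissue signature on synthetic data with a planted Cax-up
    template: recall >= 0.9, false inclusion of nulls <= 0.05."""
    from m3cax.synthetic import CohortConfig, generate_cohort

    cfg = CohortConfig(
        n_tissues=3, n_metabolites=150, noise_sd=0.3, missing_rate=0.0,
        outlier_rate=0.0, seed=1234,
        effect_templates={"early-up": (0.0, 0.0, 2.0, 2.0),
                          "null": (0.0, 0.0, 0.0, 0.0)},
        template_weights={"early-up": 0.2, "null": 0.8})
    matrix, truth = generate_cohort(cfg)
    results = []
    for tissue in ("plasma", "liver", "eWAT"):
        sub = log_transform(matrix.subset_tissue(tissue))
        results.extend(differential_tissue(sub, tissue))
    up, down = cross_tissue_signature(results)
    up_ids = {m for m, _ in up.members}
    planted = {m for m, t in truth.assignment.items() if t == "early-up"}
    nulls = {m for m, t in truth.assignment.items() if t == "null"}
    recall = len(up_ids & planted) / len(planted)
    false_incl = len((up_ids | {m for m, _ in down.members}) & nulls) / len(nulls)
    assert recall >= 0.9
    assert false_incl <= 0.05
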