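"""Isotopologue summaries of corrected tracer data.

Per (tissue, metabolite, group): mean and standard error of each
isotopologue percentage, the total labelled percentage (100 minus the mean
M+0 percentage), per-isotopologue group comparisons against the control
group (one-way ANOVA with Dunnett's many-to-one adjustment, or a two-group
Welch t when only two groups are present), and the aggregate distribution
of all labelled isotopologues over a metabolite set.

Means of percentages equal percentages of means only because each
per-sample vector sums to exactly 100; this is asserted on input.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .correction import MDV

log = logging.getLogger(__name__)


def mdvs_to_frame(mdvs: list[MDV],
                  sample_groups: dict[str, str] | None = None,
                  sample_tissues: dict[str, str] | None = None) -> pd.DataFrame:
    """Long table of MDV fractions with optional group/tissue annotation."""
    rows = []
    for m in mdvs:
        for k, f in enumerate(m.fractions):
            rows.append((m.metabolite_id, m.sample_id, k, float(f)))
    df = pd.DataFrame(rows, columns=["metabolite_id", "sample_id",
                                     "mass_shift", "fraction"])
    if sample_groups is not None:
        df["group"] = df["sample_id"].map(sample_groups)
    if sample_tissues is not None:
        df["tissue"] = df["sample_id"].map(sample_tissues)
    return df


def summarize_labelling(mdv_frame: pd.DataFrame) -> pd.DataFrame:
    """Group means and standard errors of isotopologue percentages.

    Expects a long frame with columns metabolite_id, sample_id, mass_shift,
    fraction and group (tissue optional).  Returns one row per
    (tissue, metabolite, group, mass_shift) with mean_percent, sem_percent,
    n, and labelled_total_percent (repeated per metabolite/group).
    """
    df = mdv_frame.copy()
    if "group" not in df.columns:
        raise ValueError("mdv frame must carry a 'group' column")
    if "tissue" not in df.columns:
        df["tissue"] = "all"
    sums = df.groupby(["tissue", "metabolite_id", "sample_id"])["fraction"].sum()
    if (np.abs(sums - 1.0) > 1e-3).any():
        raise ValueError("per-sample MDV fractions must sum to 1")
    df["percent"] = df["fraction"] * 100.0
    rows = []
    for (tissue, met, group), sub in df.groupby(
            ["tissue", "metabolite_id", "group"], sort=True):
        n = sub["sample_id"].nunique()
        if n == 0:
            log.warning("group %s has no samples for %s/%s", group, tissue, met)
            continue
        by_k = sub.groupby("mass_shift")["percent"]
        mean = by_k.mean()
        sem = by_k.sem(ddof=1).fillna(0.0)
        labelled_total = 100.0 - mean.get(0, 0.0)
        for k in mean.index:
            rows.append((tissue, met, group, int(k), float(mean[k]),
                         float(sem[k]), n, float(labelled_total)))
    return pd.DataFrame(rows, columns=[
        "tissue", "metabolite_id", "group", "mass_shift", "mean_percent",
        "sem_percent", "n", "labelled_total_percent"])


def compare_isotopologues(mdv_frame: pd.DataFrame, control: str = "Ctrl",
                          method: str = "dunnett") -> pd.DataFrame:
    """Per-(metabolite, isotopologue) comparison of each group vs control.

    ``method`` is ``"dunnett"`` (one-way ANOVA framework with Dunnett's
    many-to-one adjustment; reduces to a two-sample t when only one other
    group exists) or ``"dunn"`` (Kruskal-Wallis with Dunn's rank test,
    Bonferroni-adjusted across groups).
    """
    df = mdv_frame.copy()
    if "tissue" not in df.columns:
        df["tissue"] = "all"
    rows = []
    for (tissue, met, k), sub in df.groupby(
            ["tissue", "metabolite_id", "mass_shift"], sort=True):
        groups = {g: s["fraction"].to_numpy()
                  for g, s in sub.groupby("group", sort=True)}
        if control not in groups:
            raise ValueError(f"control group {control!r} absent")
        others = [g for g in groups if g != control]
        if not others:
            continue
        if any(len(groups[g]) < 2 for g in groups):
            log.warning("skipping %s/%s M+%d: a group has < 2 replicates",
                        tissue, met, k)
            continue
        ctrl_vals = groups[control]
        if method == "dunnett":
            if all(np.ptp(groups[g]) == 0 for g in groups):
                pvals = [1.0 if np.allclose(groups[g].mean(), ctrl_vals.mean())
                         else 0.0 for g in others]
            else:
                res = stats.dunnett(*[groups[g] for g in others],
                                    control=ctrl_vals)
                pvals = list(np.atleast_1d(res.pvalue))
        elif method == "dunn":
            _, kw_p = stats.kruskal(*groups.values())
            pvals = []
            for g in others:
                _, p = stats.mannwhitneyu(groups[g], ctrl_vals,
                                          alternative="two-sided")
                pvals.append(min(1.0, p * len(others)))
        else:
            raise ValueError("method must be 'dunnett' or 'dunn'")
        for g, p in zip(others, pvals):
            rows.append((tissue, met, int(k), g, control,
                         float(groups[g].mean() - ctrl_vals.mean()), float(p)))
    return pd.DataFrame(rows, columns=[
        "tissue", "metabolite_id", "mass_shift", "group", "control",
        "mean_diff", "p_value"])


def aggregate_labelled_distribution(mdv_frame: pd.DataFrame,
                                    metabolite_set: list[str] | None = None
                                    ) -> pd.DataFrame:
    """Per-group distribution over all labelled isotopologues (k >= 1) of a
    metabolite set, renormalized to sum 1 within each group."""
    df = mdv_frame.copy()
    if "group" not in df.columns:
        raise ValueError("mdv frame must carry a 'group' column")
    if metabolite_set is not None:
        df = df[df["metabolite_id"].isin(metabolite_set)]
    df = df[df["mass_shift"] >= 1]
    mean = df.groupby(["group", "metabolite_id", "mass_shift"], sort=True)[
        "fraction"].mean().reset_index()
    rows = []
    for group, sub in mean.groupby("group", sort=True):
        total = sub["fraction"].sum()
        if total <= 0:
            log.warning("group %s carries no labelling; empty distribution",
                        group)
            continue
        for _, r in sub.iterrows():
            rows.append((group, r["metabolite_id"], int(r["mass_shift"]),
                         r["fraction"] / total))
    return pd.DataFrame(rows, columns=["group", "metabolite_id", "mass_shift",
                                       "share"])
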