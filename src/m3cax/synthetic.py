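"""Synthetic cohort and labelling data with recorded ground truth.

The cohort generator emulates the study design the pipeline targets: four
experimental groups (Ctrl, NonCax, PreCax, Cax) x eight tissues x four
replicates, lognormal metabolite intensities with class-structured group
effects, missing values and injected outliers.  Effect templates mirror the
eight trajectory scenarios (early/late/gradual/transient x up/down) plus a
null template; non-cachectic tumour bearers (NonCax) carry no effect by
default.  The intensity distribution is an assumption of the generator, not
a claim about any real cohort: real MS data additionally show batch
effects, drift and intensity-dependent missingness, none of which are
simulated by default.

Determinism: one RNG stream per tissue is derived from the master seed
(PCG64 via ``numpy.random.default_rng([seed, tissue_index])``), so adding
tissues does not perturb existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import GROUPS, METABOLITE_CLASSES, TISSUES
from .datatypes import IntensityMatrix, IsotopologueSet, MetaboliteMeta, SampleMeta
from .mfa.emu import EmuSimulator
from .mfa.network import FluxNetwork, FluxVector

#: Default per-group (Ctrl, NonCax, PreCax, Cax) log-scale effects at unit
#: effect size; NonCax is 0 throughout (tumours without cachexia cause no
#: major alterations in the emulated design).
def _default_templates(effect: float = 1.0) -> dict[str, tuple[float, ...]]:
    d = effect
    up = {
        "early-up": (0.0, 0.0, d, d),
        "late-up": (0.0, 0.0, 0.0, d),
        "gradual-up": (0.0, 0.0, d / 2, d),
        "up-down": (0.0, 0.0, d, 0.0),
    }
    down = {k.replace("up", "down") if "up-" not in k else "down-up":
            tuple(-x for x in v) for k, v in up.items()}
    return {**up, **down, "null": (0.0, 0.0, 0.0, 0.0)}


_DEFAULT_CLASS_PROPORTIONS = {
    "amino acids": 0.25,
    "carbohydrates": 0.10,
    "energy": 0.20,
    "lipids": 0.20,
    "nucleosides": 0.05,
    "organoheterocyclic": 0.10,
    "other": 0.10,
}


@dataclass
class CohortConfig:
    """Generator parameters; defaults emulate the study design."""

    n_tissues: int = 8
    n_replicates: int = 4
    groups: tuple[str, ...] = GROUPS
    n_metabolites: int = 120
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_PROPORTIONS))
    effect_templates: dict[str, tuple[float, ...]] = field(
        default_factory=_default_templates)
    template_weights: dict[str, float] | None = None
    missing_rate: float = 0.05
    outlier_rate: float = 0.005
    noise_sd: float = 0.3
    baseline_mean: float = 12.0
    baseline_sd: float = 1.5
    missing_mechanism: str = "mcar"   # or "censor": left-censor low values
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_metabolites < 1 or self.n_replicates < 1 or self.n_tissues < 1:
            raise ValueError("degenerate cohort config: counts must be >= 1")
        if not 1 <= self.n_tissues <= len(TISSUES):
            raise ValueError(f"n_tissues must be in 1..{len(TISSUES)}")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name, vec in self.effect_templates.items():
            if len(vec) != len(self.groups):
                raise ValueError(f"template {name!r} must have "
                                 f"{len(self.groups)} entries")
        if self.missing_mechanism not in ("mcar", "censor"):
            raise ValueError("missing_mechanism must be 'mcar' or 'censor'")


@dataclass
class CohortTruth:
    """Ground truth recorded by the generator."""

    assignment: dict[str, str]
    flagged_outlier_cells: set[tuple[str, str]]
    true_group_means: pd.DataFrame          # metabolites x groups, log scale
    missing_cells: set[tuple[str, str]] = field(default_factory=set)


def _make_metabolites(config: CohortConfig, rng: np.random.Generator
                      ) -> list[MetaboliteMeta]:
    classes = [c for c in METABOLITE_CLASSES if c in config.class_proportions]
    probs = np.array([config.class_proportions[c] for c in classes])
    probs = probs / probs.sum()
    assigned = rng.choice(len(classes), size=config.n_metabolites, p=probs)
    mets = []
    width = len(str(config.n_metabolites))
    for i in range(config.n_metabolites):
        n_c = int(rng.integers(3, 11))
        formula = f"C{n_c}H{2 * n_c}O{int(rng.integers(2, 7))}"
        mid = f"M{i + 1:0{width}d}"
        mets.append(MetaboliteMeta(mid, f"metabolite-{i + 1}", formula,
                                   classes[assigned[i]]))
    return mets


def generate_cohort(config: CohortConfig) -> tuple[IntensityMatrix, CohortTruth]:
    """Generate a full multi-tissue cohort with recorded ground truth.

    Intensities are ``exp(baseline + group effect + N(0, noise_sd))``;
    missing cells are injected at ``missing_rate`` and outlier cells at
    ``outlier_rate`` by adding at least ``6 * noise_sd`` on the log scale.
    Identical seeds give bit-identical output.
    """
    master = np.random.default_rng([config.seed, 0])
    metabolites = _make_metabolites(config, master)
    met_ids = [m.metabolite_id for m in metabolites]

    template_names = sorted(config.effect_templates)
    if config.template_weights:
        w = np.array([config.template_weights.get(t, 0.0)
                      for t in template_names])
        w = w / w.sum()
    else:
        w = np.full(len(template_names), 1.0 / len(template_names))
    picks = master.choice(len(template_names), size=config.n_metabolites, p=w)
    assignment = {mid: template_names[k] for mid, k in zip(met_ids, picks)}
    baseline = master.normal(config.baseline_mean, config.baseline_sd,
                             size=config.n_metabolites)
    effects = np.array([config.effect_templates[assignment[mid]]
                        for mid in met_ids])
    true_means = pd.DataFrame(baseline[:, None] + effects, index=met_ids,
                              columns=list(config.groups))

    tissues = TISSUES[: config.n_tissues]
    samples: list[SampleMeta] = []
    columns: dict[str, np.ndarray] = {}
    outliers: set[tuple[str, str]] = set()
    missing: set[tuple[str, str]] = set()
    for t_idx, tissue in enumerate(tissues):
        rng = np.random.default_rng([config.seed, 1 + t_idx])
        groups = [g for g in config.groups
                  if not (tissue == "tumour" and g == "Ctrl")]
        for group in groups:
            g_idx = list(config.groups).index(group)
            for rep in range(1, config.n_replicates + 1):
                sid = f"{tissue}_{group}_{rep}"
                log_vals = (true_means.iloc[:, g_idx].to_numpy()
                            + rng.normal(0.0, config.noise_sd,
                                         config.n_metabolites))
                vals = np.exp(log_vals)
                samples.append(SampleMeta(sid, tissue, group, rep))
                columns[sid] = vals
        # missingness, then outliers among observed cells
        sids = [s.sample_id for s in samples if s.tissue == tissue]
        n_cells = config.n_metabolites * len(sids)
        if config.missing_rate > 0:
            if config.missing_mechanism == "mcar":
                mask = rng.random((config.n_metabolites, len(sids)))
                hit = mask < config.missing_rate
            else:
                block = np.column_stack([columns[s] for s in sids])
                cut = np.quantile(block, config.missing_rate)
                hit = block <= cut
            for r, c in np.argwhere(hit):
                columns[sids[c]][r] = np.nan
                missing.add((met_ids[r], sids[c]))
        if config.outlier_rate > 0 and config.noise_sd > 0:
            n_out = rng.binomial(n_cells, config.outlier_rate)
            flat = rng.choice(n_cells, size=n_out, replace=False)
            for f in flat:
                r, c = divmod(int(f), len(sids))
                if np.isnan(columns[sids[c]][r]):
                    continue
                bump = (6.0 + rng.exponential(1.0)) * config.noise_sd
                columns[sids[c]][r] *= np.exp(bump)
                outliers.add((met_ids[r], sids[c]))

    values = pd.DataFrame({s.sample_id: columns[s.sample_id] for s in samples},
                          index=met_ids)
    matrix = IntensityMatrix(values, samples, metabolites, scale="raw")
    truth = CohortTruth(assignment, outliers, true_means, missing)
    return matrix, truth


def generate_labelling(
    network: FluxNetwork,
    true_fluxes: FluxVector | dict[str, float],
    mdv_noise_sd: float = 0.03,
    n_samples: int = 4,
    seed: int = 0,
    sample_prefix: str = "S",
    total_intensity: float = 1e6,
    convolve_natural_abundance: bool = False,
) -> tuple[IsotopologueSet, FluxVector]:
    """Simulate noisy isotopologue measurements from ground-truth fluxes.

    Steady-state MDVs of the network's measured metabolites are perturbed
    per fraction with Gaussian noise of the given standard deviation
    (truncated at 0), renormalized to sum 1, and scaled to intensities.
    With ``convolve_natural_abundance`` the tracer MDVs are pushed through
    the forward natural-abundance model first, emulating what a mass
    spectrometer would actually record; the correction stage then inverts
    it.  The balanced ground-truth flux vector is returned for recovery
    tests.
    """
    if isinstance(true_fluxes, dict):
        fluxes = network.complete_fluxes(true_fluxes)
    else:
        fluxes = true_fluxes
    fluxes.check_balance(network, atol=1e-6)
    sim = EmuSimulator(network)
    mdvs = sim.simulate(fluxes.as_array(network))
    rng = np.random.default_rng([seed, 42])
    entries: dict[tuple[str, str], np.ndarray] = {}
    metas: dict[str, MetaboliteMeta] = {}
    for met, mdv in mdvs.items():
        formula = network.formulas.get(met, f"C{len(mdv) - 1}")
        metas[met] = MetaboliteMeta(met, met, formula, "energy")
        if convolve_natural_abundance:
            from .correction import CorrectionModel, build_correction_matrix

            mat = build_correction_matrix(CorrectionModel(formula))
            mdv = mat @ mdv
        for i in range(1, n_samples + 1):
            noisy = mdv + rng.normal(0.0, mdv_noise_sd, size=len(mdv)) \
                if mdv_noise_sd > 0 else mdv.copy()
            noisy = np.maximum(noisy, 0.0)
            noisy = noisy / noisy.sum()
            entries[(met, f"{sample_prefix}{i}")] = noisy * total_intensity
    return IsotopologueSet(entries, metas), fluxes


# ---------------------------------------------------------------------------
# deterministic toy fixtures for unit tests

def _liver_samples(n_per_group: int = 4) -> list[SampleMeta]:
    return [SampleMeta(f"liver_{g}_{r}", "liver", g, r)
            for g in GROUPS for r in range(1, n_per_group + 1)]


def _fixture_missingness_boundary() -> IntensityMatrix:
    """16 samples; one metabolite with exactly 4/16 missing (25%, kept) and
    one with 5/16 (removed), plus complete donor metabolites."""
    samples = _liver_samples()
    rng = np.random.default_rng(7)
    n_met = 8
    mets = [MetaboliteMeta(f"M{i+1}", f"m{i+1}", "C6H12O6", "other")
            for i in range(n_met)]
    vals = np.exp(rng.normal(10, 0.2, size=(n_met, 16)))
    vals[0, :4] = np.nan       # exactly 25%
    vals[1, :5] = np.nan       # 31.25%
    df = pd.DataFrame(vals, index=[m.metabolite_id for m in mets],
                      columns=[s.sample_id for s in samples])
    return IntensityMatrix(df, samples, mets, scale="raw")


def _fixture_rsd_ladder() -> IntensityMatrix:
    """10 metabolites with strictly increasing RSD in the Ctrl condition
    and negligible spread elsewhere."""
    samples = _liver_samples()
    mets = [MetaboliteMeta(f"M{i+1:02d}", f"m{i+1}", "C5H10O5", "other")
            for i in range(10)]
    vals = np.empty((10, 16))
    # Ctrl columns 0..3: spread scaled to give RSD ~ 0.013 * (i+1); the
    # other conditions share one identical spread so that no metabolite
    # strictly exceeds their common RSD percentile there
    base = np.array([-1.5, -0.5, 0.5, 1.5])
    for i in range(10):
        vals[i, :4] = 100.0 + base * (i + 1)
        vals[i, 4:8] = vals[i, 8:12] = vals[i, 12:16] = 100.0 + base * 0.5
    df = pd.DataFrame(vals, index=[m.metabolite_id for m in mets],
                      columns=[s.sample_id for s in samples])
    return IntensityMatrix(df, samples, mets, scale="raw")


def _fixture_tukey_shift() -> IntensityMatrix:
    """4 groups x n=4; the Cax group of metabolite M1 is shifted by 5 SD."""
    samples = _liver_samples()
    rng = np.random.default_rng(13)
    n_met = 12
    mets = [MetaboliteMeta(f"M{i+1:02d}", f"m{i+1}", "C4H8O4", "other")
            for i in range(n_met)]
    log_vals = rng.normal(10, 1.0, size=(n_met, 16))
    cax_cols = [i for i, s in enumerate(samples) if s.group == "Cax"]
    log_vals[0, cax_cols] += 5.0
    # Ctrl and NonCax of the shifted metabolite are literally identical, so
    # their pairwise contrast has zero mean difference (p ~ 1)
    ctrl_cols = [i for i, s in enumerate(samples) if s.group == "Ctrl"]
    nc_cols = [i for i, s in enumerate(samples) if s.group == "NonCax"]
    log_vals[0, nc_cols] = log_vals[0, ctrl_cols]
    df = pd.DataFrame(np.exp(log_vals), index=[m.metabolite_id for m in mets],
                      columns=[s.sample_id for s in samples])
    return IntensityMatrix(df, samples, mets, scale="raw")


_FIXTURES = {
    "missingness_boundary": _fixture_missingness_boundary,
    "rsd_ladder": _fixture_rsd_ladder,
    "tukey_shift": _fixture_tukey_shift,
}


def build_toy_fixture(name: str) -> IntensityMatrix:
    """In-memory fixture; see generate_toy_fixture for the on-disk variant."""
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; "
                         f"known: {sorted(_FIXTURES)}")
    return _FIXTURES[name]()


def generate_toy_fixture(name: str, out_dir) -> dict[str, str]:
    """Write a named deterministic fixture to ``out_dir``; returns paths."""
    from pathlib import Path

    from .io import write_intensity_table

    matrix = build_toy_fixture(name)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": str(out / f"{name}_values.csv"),
        "samples": str(out / f"{name}_samples.csv"),
        "metabolites": str(out / f"{name}_metabolites.csv"),
    }
    write_intensity_table(matrix, paths["values"], paths["samples"],
                          paths["metabolites"])
    return paths
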