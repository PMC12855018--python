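# m3cax

Multi-tissue stable-isotope tracer-metabolomics analysis of cancer-cachexia
progression, as a tested, reusable Python pipeline.

Cancer cachexia is a wasting syndrome that rewires metabolism across many
organs long before weight is lost.  Studying it with tracer metabolomics
means profiling metabolite levels and ¹³C-labelling patterns in several
tissues of tumour-bearing mice (healthy controls, non-cachectic,
pre-cachectic and cachectic groups) and asking three questions: *which
metabolites change* (per-tissue differential analysis and a cross-tissue
signature), *how they change over disease pseudo-time* (fuzzy trajectory
clustering into eight up/down scenario groups), and *which fluxes explain
the labelling* (¹³C metabolic flux analysis of the TCA network).  `m3cax`
implements that full chain for analysts working with isotopologue and
intensity tables:

- **Isotopologue correction** — natural-abundance and tracer-purity
  deconvolution of measured M+0…M+C intensities by non-negative least
  squares, yielding mass isotopomer distribution vectors (MDVs).
- **Preprocessing** — log transform, mean + 4·SD outlier masking, > 25%
  missingness filter, 80th-percentile RSD filter per condition, knn
  imputation; per tissue, with a tallied report.
- **Differential analysis** — one-way ANOVA + Tukey HSD per metabolite,
  log₂ fold changes, and the cross-tissue cachexia signature (significant
  and direction-consistent versus both control groups in ≥ 2 target
  tissues).
- **Trajectory clustering** — z-standardized (baseline, pre-cachectic,
  cachectic) profiles sorted into 8 scenario clusters by
  template-initialized, variance-sensitive fuzzy c-means with Xie–Beni
  validation; membership rankings and Sankey-ready contribution tables.
- **¹³C MFA** — an atom-transition network parser, a compiled EMU
  simulator for steady-state MDVs, weighted least-squares flux fitting
  (citrate synthase V12 as reference = 100, 3% MDV standard error), χ²
  goodness of fit, and Monte-Carlo 95% confidence intervals with the
  interval-overlap significance rule.
- **Synthetic cohorts** — a generator that emulates the study design
  (4 groups × 8 tissues × 4 replicates, lognormal intensities, scenario
  effect templates, missingness, outliers, labelling from ground-truth
  fluxes) with full determinism per seed, so every stage is testable
  without downloads.

The flux model at the core minimizes

```
SSR(v) = Σ_i ( (MDV_sim,i(v) − MDV_meas,i) / SE )²,   SE = 0.03
```

over the free fluxes (pyruvate carboxylase V9, pyruvate dehydrogenase V10,
glutamine entry V16), with all dependent net fluxes determined by
steady-state stoichiometric balance and the reference flux pinned
(V12 = 100).  `MDV_sim` comes from EMU (elementary metabolite unit)
decomposition; symmetric succinate/fumarate are scrambled 50:50.

## Worked example

```python
import numpy as np
from m3cax.mfa import default_network, EmuSimulator, fit_fluxes, monte_carlo_ci
from m3cax.mfa.fit import perturb_mdvs

net = default_network()                       # glycolysis -> TCA, V12 = 100
truth = net.complete_fluxes({"V9": 30, "V10": 70, "V16": 20})
mdvs = EmuSimulator(net).simulate(truth.as_array(net))
meas = perturb_mdvs(mdvs, 0.03, np.random.default_rng(2024))  # noisy data

fit = fit_fluxes(net, meas, mdv_se=0.03, seed=1, n_starts=3)
fit = monte_carlo_ci(net, meas, fit, n_draws=200, seed=2)
print(f"SSR={fit.ssr:.1f} dof={fit.dof} chi2_p={fit.chi2_p:.3f}")
for rid in ("V9", "V10", "V16", "V12"):
    lo, hi = fit.ci[rid]
    print(f"{rid}: {fit.fluxes.values[rid]:6.1f}  95% CI [{lo:.1f}, {hi:.1f}]")
```

prints

```
SSR=19.4 dof=19 chi2_p=0.428
V9:   18.5  95% CI [4.3, 34.2]
V10:   69.4  95% CI [63.3, 76.1]
V16:   18.1  95% CI [14.4, 22.6]
V12:  100.0  95% CI [100.0, 100.0]
```

— every simulated truth (V9 = 30, V10 = 70, V16 = 20) lies inside its 95%
interval, the SSR matches its χ² expectation (19.4 at 19 degrees of
freedom, p ≈ 0.43), and the citrate synthase reference is exactly 100 by
construction.  The anaplerotic flux V9 is the least constrained — its
point estimate scatters the most at 3% MDV noise, which is exactly what
its wide interval reports.

The full pipeline on a synthetic cohort:

```
m3cax run-all --seed 1 --out results/
```

writes per-stage CSVs (differential contrasts, signatures, cluster
centroids/members/contributions, labelling summaries, flux fit) plus a
manifest stamped with the config hash and seed.  A network file for your
own model follows the grammar documented in `docs/methods.md`:

```
V10: PYR (abc) -> CO2 (a) + ACCOA (bc)
symmetric: SUC, FUM
substrate: GLC = [1,1,1,1,1,1]
reference: V12 = 100
free: V9, V10, V16
measure: CIT, SUC, FUM, MAL
```

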