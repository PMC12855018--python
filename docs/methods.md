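# Methods

`m3cax` re-implements, as a tested and reusable pipeline, a multi-tissue
stable-isotope tracer-metabolomics analysis of cancer-cachexia
progression: natural-abundance correction of isotopologue intensities,
matrix preprocessing, per-tissue differential analysis with a cross-tissue
signature, pseudo-time fuzzy trajectory clustering, labelling summaries,
and ¹³C metabolic flux analysis (MFA) of a glycolysis→TCA network.  Every
stage is exercised end-to-end on a synthetic cohort generator with
recorded ground truth, so the whole pipeline is testable without any
external data.

## Study design being emulated

Four experimental groups of mice — Ctrl (healthy), NonCax (tumour-bearing,
non-cachectic), PreCax (tumour-bearing, pre-cachectic) and Cax (cachectic)
— with n = 4 animals per group, profiled across eight tissues (plasma,
liver, eWAT, iWAT, heart, gastrocnemius, soleus, tumour).  Tumour tissue
exists only in tumour-bearing animals, so it never carries the Ctrl group.
Pseudo-time orders groups as baseline → pre-cachectic → cachectic, with
NonCax standing in for the missing Ctrl baseline in tumour.

## Isotopologue correction

Measured mass-shift intensities mix the tracer signal with naturally
occurring heavy isotopes of every element and with tracer impurity.  The
low-resolution correction builds a (C+1)×(C+1) matrix whose column *j* is
the expected measured distribution of a species with exactly *j*
tracer-derived labels: the convolution of (a) the natural-abundance
mass-shift distribution of all non-tracer elements, (b) natural abundance
of the C−j unlabelled tracer positions and (c) the binomial purity
distribution of the *j* labelled positions.  Shifts beyond C are
truncated, so columns sum to ≤ 1.  The system is inverted by non-negative
least squares (`scipy.optimize.nnls`) and the solution renormalized to the
simplex; the result is invariant to uniform scaling of the input.
Defaults: ¹³C natural abundance 0.0107 (full tables pinned in
`m3cax.constants`), tracer purity 1.0 (configurable; the purity actually
used by a given tracer lot is rarely printed).  High-resolution elemental
separation and tandem-MS fragments are out of scope.

## Preprocessing

Five stages per tissue, in this order, with these defaults:

1. **Log transform** (natural log).  Zero or negative observed values are
   a hard error — no silent pseudo-count.
2. **Outlier masking**: per metabolite over all samples of the tissue, on
   the log scale, values strictly greater than mean + 4·SD are set to
   missing.  One pass, no iteration.  A corollary worth knowing: a single
   spike among n values can reach at most z = (n−1)/√n, which exceeds 4
   only for n ≥ 18 — at n = 16 samples per tissue the rule can only fire
   when several values are spread out, never for one lone spike.
3. **Missingness filter**: metabolites with *strictly more than* 25%
   missing values across all samples of the tissue are removed (25%
   exactly is kept).
4. **RSD filter**: per condition (= experimental group within the
   tissue), RSD = sd/mean over observed *raw-scale* values (the CV of log
   values is not scale-free; the raw matrix is carried alongside).  A
   metabolite is removed iff its RSD strictly exceeds the 80th percentile
   of the per-condition RSD distribution in at least one condition.
   Percentiles use linear interpolation between order statistics (pinned
   in `m3cax.constants.PERCENTILE_METHOD`).  Two structural properties of
   a percentile-based cut: it removes ~20% of metabolites per condition
   *by construction* (~59% across four independent conditions on
   homogeneous data), and it is **not idempotent** — the threshold
   recomputed on survivors keeps biting.  Cells with fewer than 2
   observed values contribute no RSD.
5. **knn imputation** (k = 5): donors are the k nearest metabolite rows by
   Euclidean distance over mutually observed samples (NaN-Euclidean
   scaling), restricted to donors observed in the target sample,
   contributing an unweighted mean.  A cell with no eligible donor falls
   back to the metabolite's own observed mean (counted in the report).

The outlier rule's grouping (per tissue, log scale) and k are design
choices where the published description is silent; both are configurable.

## Differential analysis and the cross-tissue signature

Classical one-way ANOVA per metabolite across the four groups, followed by
Tukey's honestly-significant-difference procedure for all six pairwise
contrasts (`scipy.stats.tukey_hsd`; Tukey–Kramer for unbalanced groups).
No across-metabolite multiplicity correction is applied — Tukey corrects
across contrasts only.  Fold changes are reported in log₂ units.

A metabolite joins the **up (down) cachexia signature** iff, in at least
two of the seven cachexia target tissues (tumour excluded), both the
Cax–Ctrl and Cax–NonCax Tukey contrasts have p < 0.05 *and* positive
(negative) mean differences in both contrasts in those same tissues.  The
direction-agreement requirement is the stricter reading of "commonly
up/down" and can be relaxed by flag; α is per-tissue configurable (muscle
analyses sometimes use a looser 0.1).

Isotopologue group comparisons use one-way ANOVA with Dunnett's
many-to-one adjustment versus Ctrl (`scipy.stats.dunnett`), reducing to a
two-sample t when only two groups exist; a Kruskal–Wallis/Dunn rank
fallback is available by flag.  Means ± s.e.m. are reported.

## Trajectory clustering

Per metabolite and tissue, the pseudo-time profile is the ordered 3-vector
of group means (baseline, pre-cachectic, cachectic), z-standardized across
the three points (population SD) so only shape matters; constant profiles
are dropped.  Profiles are clustered into **eight scenario groups** —
{early, late, gradual, transient} × {up, down} — by fuzzy c-means with
c = 8, fuzzifier m = 2, tolerance 1e-6, max 300 iterations, and centroids
initialized at the eight standardized scenario templates (no random
restarts: the procedure is deterministic).  Variance sensitivity is
implemented as per-cluster distance scaling by the cluster's current
membership-weighted dispersion, floored at 1e-3 to avoid collapse; this is
an interpretation of "variance-sensitive clustering" and is switchable.
Zero-distance profiles receive full membership in their cluster.  Validity
is assessed by the Xie–Beni index (membership-weighted within-cluster
scatter over n × minimum squared centroid separation; lower is better);
a generic-c fuzzy c-means with farthest-point seeding supports selecting c
by Xie–Beni, which recovers c = 8 on data generated from the eight
templates.  Reporting: per-cluster members ranked by membership
(deterministic lexicographic tie-break, top 10 by default, minimum
membership 0.5 gate configurable) and Sankey-ready tissue×cluster and
cluster×class contingency tables.

## ¹³C metabolic flux analysis

**Network.**  Plain-text atom-transition grammar
(`V10: PYR (abc) -> CO2 (a) + ACCOA (bc)`), with directives for symmetric
molecules, substrate labelling (per-carbon label probabilities), the
reference flux, free/fixed fluxes, measured metabolites and formulas.  The
shipped default implements lumped glycolysis (GLC → 2 PYR), pyruvate
efflux, pyruvate carboxylase V9, pyruvate dehydrogenase V10, unlabelled
acetyl-CoA inflow V11 (fatty-acid oxidation / ketogenic amino acids),
citrate synthase V12 (reference = 100), lumped aconitase/IDH, glutamine
entry V16/V17, OGDH V18, SDH V19, FH V20, MDH V21, cataplerotic OAA
efflux, and CO₂ efflux, under a fully labelled [¹³C₆]glucose tracer.
Succinate and fumarate are symmetric and scrambled 50:50 at production.
Two modelling choices matter for the anaplerotic M+3 signature:
pyruvate carboxylase draws its CO₂ from an *unlabelled bicarbonate*
substrate pool (the body bicarbonate pool is an effectively infinite
unlabelled dilution; recycling tracer-derived CO₂ would shift PC products
to M+4), and MDH/FH carry fixed reverse-exchange reactions (100 on the
reference scale) because both enzymes operate near equilibrium in vivo —
without back-exchange the PC-derived M+3 label would never reach
malate/fumarate.  Free fluxes are V9, V10, V16; all other net fluxes
follow from steady-state stoichiometric balance with the reference pinned.

**Simulation.**  Steady-state mass isotopomer distribution vectors (MDVs)
are computed by EMU (elementary metabolite unit) decomposition: the
full-carbon EMUs of the measured metabolites are traced back through all
producing reactions, convolutions split multi-reactant origins, EMUs are
grouped by size, and one small linear balance system per size is solved in
increasing order.  The decomposition is compiled once per target set;
evaluating a new flux vector costs ~0.3 ms, which keeps fitting and
Monte-Carlo resampling cheap.  The simulator is verified exhaustively
against a brute-force positional-isotopomer fixed-point oracle.

**Fitting.**  Free fluxes minimize Σ((sim − meas)/SE)² with SE = 0.03 per
MDV fraction (absolute), non-negativity bounds, and penalty residuals for
negative dependent fluxes, using bounded trust-region least squares from
several seeded feasible starts (best optimum wins).  Goodness of fit is
the upper-tail χ² probability of the weighted SSR at dof = number of
fitted fractions − number of free fluxes.  95% confidence intervals are
percentile intervals over Monte-Carlo refits: each draw perturbs the
measured fractions with Gaussian noise of the stated SE, clips at 0,
renormalizes, and refits from the point estimate with a damped
Gauss–Newton polish (warm-started, frozen-structure, a handful of
iterations).  CIs are flagged unreliable if more than 20% of refits fail.
Two fluxes differ at P < 0.05 when their 95% intervals do not overlap.
Non-stationary MFA, flux variability analysis and compartmentation are out
of scope (steady-state approximation).

## Synthetic data generator

Intensities are lognormal: exp(baseline + group effect + N(0, σ)), with
baseline log-mean ~ N(12, 1.5), noise σ = 0.3, group effects drawn from
eight scenario templates (unit effect size, NonCax = 0 — non-cachectic
tumours cause no major alterations in the emulated design) plus a null
template.  Missing cells are injected completely at random at rate 0.05
(an intensity-dependent left-censoring mode exists but is off by default,
keeping filter behaviour analytic); outlier cells at rate 0.005 add
(6 + Exp(1))·σ on the log scale.  One RNG stream per tissue is derived
from the master seed (`default_rng([seed, tissue_index])`), so adding
tissues never perturbs existing ones; identical seeds give bit-identical
output.  Labelling data are simulated from ground-truth fluxes
(V9 = 30, V10 = 70, V16 = 20 by default) via the EMU simulator, perturbed
per fraction with truncated Gaussian noise (sd 0.03), renormalized, and
scaled to intensities; optionally pushed through the forward
natural-abundance model so the correction stage inverts something real.
The generator emulates the statistical structure the analysis assumes —
it does not simulate batch effects, chromatographic drift, annotation
errors or intensity-dependent missingness (by default), so green tests
demonstrate correctness of the procedures, not robustness to every
artefact of real MS data.

## Validation and problem sizes

The simulation suites use problem sizes chosen to make sampling error
small while keeping the default test run quick: 200 datasets × 200
Monte-Carlo draws for CI coverage (binomial 99% bounds around 95% are
roughly 91–99% at 200 replicates; measured ≈ 95–96%), 60 replicates for
the SSR-vs-dof calibration, 16 replicates × 3 PC:PDH scenarios for
recovery-within-CI, 2000 metabolites for type-I-error calibration, and
10⁴–2×10⁴ draws for the permutation and studentized-range oracles.

## Known limitations

- The published flux network (supplementary material) is not recoverable
  from the main text; the default network implements the named fluxes with
  interpolated numbering and is swappable via the network file.
- The exact variance-sensitivity mechanism and membership cutoff of the
  cited clustering method are interpretations, exposed as configuration.
- Percentile CIs inherit the usual bootstrap bias near parameter bounds
  (e.g. a true flux close to 0).
- Whether fitting should use per-animal or per-group-mean MDVs is not
  specified; per-group-mean is the default, per-sample tables are
  accepted.
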