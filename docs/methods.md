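# Methods

This note documents the models, the synthetic-data generating process, the
numerical choices, and the known limitations of `gametherm`.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Thermal performance curves

A TPC is a unimodal relationship between temperature and a biological rate.
The registry (`gametherm.tpc.MODEL_REGISTRY`) ships ten curve families that
cover the shapes used in the ecological-physiology literature: `quadratic`,
`gaussian`, `modifiedgaussian` (gaussian with a shape exponent *b*, flat-topped
for b > 2), `briere2`, `sharpeschoolhigh` (Boltzmann rise with high-temperature
inactivation; reference temperature fixed at 15 °C, Boltzmann constant
8.617 × 10⁻⁵ eV K⁻¹), `ratkowsky`, `weibull`, `lactin2`, `rezende`
(Q10 rise with quadratic decline above a threshold), and `flinn`.  The
registry is a plain mapping and is extensible; the three families named first
are the ones most analyses of fertilization/velocity/motility end up
selecting and are always included in the default candidate set.

### Fitting

Bounded nonlinear least squares (`scipy.optimize.least_squares`, trust-region
reflective).  Multistart: the first start comes from data-driven heuristics
(peak location from lightly smoothed rates, peak height from the max rate),
the rest are uniform draws within the per-model bounds; 10 starts by default,
all seeded.  The best converged start by RSS wins; a model whose starts all
fail is reported `converged=False` and excluded from ranking with a logged
reason, never silently dropped.

### Model selection

AICc with the Gaussian-likelihood convention: for RSS from *n* points and a
model with *p* curve parameters, k = p + 1 (the residual variance counts),

log L̂ = −n/2·(ln 2π + ln(RSS/n) + 1),  AICc = −2 log L̂ + 2k + 2k(k+1)/(n−k−1).

**The k convention matters**: published AICc values differ by exactly whether
the variance parameter is counted, so it is stated here and asserted in the
unit tests (RSS = 1, n = 10, k = 3 → 15.35292).  Models with n − k − 1 ≤ 0,
or with RSS = 0 (no defined likelihood scale), are excluded with an explicit
status.  Ties break by fewer parameters, then model name, making the ranking
invariant to candidate order.

### Derived parameters

r_max and T_opt are located by a dense grid scan (default step 0.01–0.05 °C)
refined by bounded scalar maximization between the bracketing grid points.
Thermal breadth T_br is the total width of the region where the (zero-clamped)
rate is ≥ 80 % of r_max; region edges are refined by Brent root bracketing,
so breadth accuracy is limited by the root tolerance (1e−10), not the grid
step.  Negative fitted rates (quadratic tails) are clamped to zero for
derived parameters only, never during fitting.  Non-contiguous
super-threshold regions are summed and flagged `contiguous=False`; a peak or
breadth edge pinned to the grid boundary sets `boundary_censored=True`, and
the curve is never evaluated outside the configured grid for breadth claims.

### Bootstrap uncertainty

Residual bootstrap: centered residuals are resampled with replacement, added
to the fitted values, the model is refitted starting from the original
estimates, derived parameters are recomputed, and percentile intervals are
taken (default 95 %).  Two standard refinements:

1. residuals are inflated by √(n/(n−p)) to undo the scale shrinkage caused by
   fitting p curve parameters;
2. for **proportion traits** (fertilization, motility) the resampling is made
   heteroscedasticity-consistent: residuals are standardized by the local
   binomial standard error √(p̂(1−p̂)/n_eggs) before resampling and rescaled
   at the destination point (`binomial_residual_scale`).  Binomial noise is
   far smaller at the curve's tails (p̂ near 0 or 1) than on its slopes, and
   a calibration simulation in the test suite shows the plain exchangeable
   scheme undercovers T_opt (≈ 0.84 empirical coverage at nominal 0.95 under
   the 12-temperature, 150-egg design) while the scaled scheme restores
   ≈ 0.92–0.96.

Refit failures are skipped and counted; a failure rate above 50 % marks the
intervals unreliable.

## Sperm kinematics

VCL is the chord-sum path length divided by elapsed time, (n−1)/frame-rate.
No smoothing is applied before chord summation by default (an optional
moving-average smoother exists for noisy digitizations).  Motility uses a
strictly-greater threshold, default 5 μm s⁻¹: a literal "VCL > 0" rule is
unusable on digitized tracks because tracking jitter gives stationary cells a
small nonzero path length, so the threshold encodes the tracking noise floor
and is configurable.  Sample summaries average the VCL of motile tracks only
(continuously swimming sperm); `include_immotile=True` averages all tracks.
A sample with no motile track reports `mean_vcl = 0` with an explicit
`all_immotile` flag.

## Fertilization kinetics

The collision (Vogel-type) model: φ = 1 − exp(−(βS₀/β₀E₀)(1 − e^(−β₀E₀t))),
with β₀ = υσ₀.  Units are normalized to mm³ and seconds; 1 μl = 1 mm³ makes
per-μl concentrations numerically per-mm³, and υ (μm s⁻¹) × σ₀ (μm²) converts
to mm³ s⁻¹ by the exact factor 10⁻⁹.  The β₀E₀ → 0 limit is continued by
series (φ → 1 − e^(−βS₀t)) so degenerate inputs stay exact.  Only the ratio
β/β₀ is identifiable from fertilization data; it is estimated by bounded
scalar least squares (the objective is monotone in predicted φ, so a single
bounded search suffices; the search upper bound is set from the closed-form
single-observation inversion ratio = −ln(1−φ)E₀/(S₀(1−e^(−β₀E₀t)))).  Its
standard error comes from the Gauss–Newton curvature at the optimum.
Observations with φ exactly 0 or 1 carry no information about the ratio; if
all are degenerate, fitting is rejected as non-identifiable.

E₀, σ₀, and assay concentrations must be supplied; the shipped defaults
(egg diameter 130 μm → σ₀ ≈ 1.33 × 10⁴ μm²; S₀ ≈ 0.455 μl⁻¹, the dilution of
50 μl of a 10⁵ sperm ml⁻¹ stock into an 11 ml dish; E₀ = 0.02 μl⁻¹; t = 900 s)
are illustrative protocol-scale numbers, not fitted empirical values.  Both a
global ratio fit and per-condition closed-form inversions are available.

## Aligned-rank-transform factorial ANOVA

For each effect (A, B, A×B) of a balanced two-factor table the responses are
aligned by cell-mean algebra — residual from the cell mean plus the estimated
target effect only — then midranked, and a standard balanced two-way
fixed-effects ANOVA runs on the ranks; only the target effect's F is
interpreted.  Diagnostics exposed per effect: the aligned-response sums
(exactly zero up to float error) and the "stripped" F of the non-target
effects on the same aligned-ranked data (≈ 0 for noiseless constructions).
Fully tied aligned ranks (a noiseless null effect) short-circuit to F = 0,
p = 1 rather than 0/0.  Unbalanced tables and empty cells are rejected —
the alignment algebra is only exact for balanced designs.

Biological replicates enter as single rows (technical replicates are averaged
upstream), so a 3 × 3 design with 3 pairs per cell yields the classic
(2, 18) / (4, 18) df structure.  A pair-as-block option is deliberately not
the default: replicate-level means without a random pair effect reproduce the
standard reporting df for this design.

Posthoc contrasts are marginal-mean t contrasts **on the aligned ranks for
the target factor**, using the rank-ANOVA MS_error and its error df (the
estimated-marginal-means construction) — a two-sample t test on the same
ranks was measured anti-conservative in a null simulation (familywise ≈ 0.09
after Bonferroni) and is not used.  Bonferroni: p_adj = min(1, m·p_raw) over
the m level pairs.  Cohen's d (pooled SD) is computed on the raw response
scale, with magnitude labels on the conventional small → huge scale.
Spearman's ρ is the Pearson correlation of midranks with the two-sided
t-approximation p-value (t = ρ√((n−2)/(1−ρ²)), n−2 df).

## Synthetic data generator

The generator emulates the two assay layouts exactly: 12 temperatures
(8–38 °C) × 3 pairs × 3 technical replicates of 50 eggs for sand dollars, 7
temperatures for urchins, and a 3 × 3 temperature × pH factorial where each
pair sits under one temperature but crosses all pH levels (the pair's random
shift is shared across its pH cells, inducing the within-pair correlation the
design implies).  Fertilized counts are binomial with success probability
expit(logit(TPC(T)) + pH offset + pair shift); pair heterogeneity is a normal
shift on the logit (SD 0.3 by default), the simplest exchangeable structure
that keeps probabilities in (0, 1).  pH acts as per-level additive logit
offsets (−1.5, −0.6, 0 at pH 7.1/7.5/7.9), mirroring the three-level
treatment rather than a continuous slope.  Individual sperm speeds are
normal truncated at zero (CV 0.2) around a TPC-shaped mean with Bernoulli
motility; circular tracks are sampled at 60 Hz for 10 s with per-frame turn
angle θ = 2 asin(v/(2rf)), which makes the chord-sum velocity equal the
requested speed to machine precision (requests implying θ ≥ π are rejected as
undersampled).

Default truth curves are **synthetic illustrations** chosen for qualitative
realism (unimodal, optimum near 14–18 °C, fertilization plateau ≈ 0.95 with
breadth ≈ 18 °C, velocity peak 350 μm s⁻¹ at 13.9 °C, motility peak 0.8):
they are not fitted to any published dataset, and no between-pair variance or
egg-concentration values are claimed as empirical.  What the generator does
**not** emulate: sperm aging over the assay, chemoattraction, temperature
effects on egg receptivity, video digitization noise, or carbonate-system
chemistry — so passing tests validate the statistical machinery under the
stated generating process, not organism-level realism.

## Problem sizes used in validation

The validation suite runs each stochastic check at sizes chosen to give
stable Monte-Carlo estimates on a single CPU: 100 simulations for T_opt
recovery and AICc selection, 200 simulations × 200 bootstrap draws for
interval coverage (a scaled-down setting of the 1000-iteration fitting /
5000-draw CI bootstrap used at publication scale — both entry points accept
any `n_boot` ≥ 100), and 1000 simulations for ART type-I-error calibration.
Coverage assertions use the binomial-scaled bootstrap described above.

## Known limitations

- Weighted NLS and Bayesian TPC fitting are out of scope; all fits are
  ordinary least squares on replicate-level means.
- The ART implementation covers exactly two crossed fixed factors; no mixed
  models, no >2-way designs.
- The kinetics model ignores polyspermy, sperm limitation in the field, and
  chemoattraction; it is the single-ratio collision model only.
- Breadth for multimodal fitted curves is a total measure across regions;
  interpreting it requires the `contiguous` flag.
- `sharpeschoolhigh` and `rezende` can be weakly identified on narrow
  temperature ranges; the exclusion log and `converged` flags should be
  inspected when using the full registry on small datasets.
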