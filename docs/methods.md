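# Methods

This note records the models, numerical choices and defaults behind
`surromark`, and what the synthetic validation does and does not establish.

## Synthetic cohort model

Each tumor i carries a subtype s<sub>i</sub> drawn from a prevalence vector
over {LumA, LumB, mApo, Basal} (default 0.45 / 0.25 / 0.10 / 0.20, i.e.
70% luminal). Two latent activities are drawn conditional on subtype:

* ER activity a<sub>i</sub> ~ N(μ<sup>ER</sup><sub>s</sub>, 0.5²) with
  subtype means 3.5 (LumA), 3.0 (LumB), 0.3 (mApo), 0.0 (Basal);
* GATA3 activity g<sub>i</sub> ~ N(μ<sup>G3</sup><sub>s</sub>, 0.5²) with
  means 3.0 / 2.8 / 0.2 / 0.0 — except that a fraction (default 0.4) of
  molecular apocrine tumors draws from a high component with mean 2.5,
  producing the GATA3-high, CAXII-expressing ER-negative subset.

Observed log2 expression of gene g is a linear readout,
x<sub>ig</sub> = β<sub>g</sub> + w<sup>ER</sup><sub>g</sub>·a<sub>i</sub> +
w<sup>G3</sup><sub>g</sub>·g<sub>i</sub> + ε,
ε ~ N(0, σ<sub>g</sub>²), except that with subtype-dependent probability
the readout *drops out* to β<sub>g</sub> + ε (silencing independent of the
latent activities). Default gene models:

| gene  | baseline | w_ER | w_GATA3 | σ   | dropout                 |
|-------|----------|------|---------|-----|-------------------------|
| ESR1  | 6.0      | 1.5  | 0.5     | 0.6 | —                       |
| PGR   | 5.0      | 1.6  | 0       | 1.1 | LumA 0.06, LumB 0.30    |
| CA12  | 5.5      | 0.9  | 0.9     | 0.7 | —                       |
| TFF1  | 4.5      | 1.4  | 0       | 1.5 | —                       |
| GREB1 | 5.0      | 1.3  | 0       | 0.8 | —                       |
| FOXA1 | 6.5      | 0.5  | 0.9     | 0.7 | —                       |
| GATA3 | 6.0      | 0.2  | 1.3     | 0.6 | —                       |
| decoys| 7.0      | 0    | 0       | 1.0 | —                       |

These values are phenomenological, chosen once so the generated cohorts
show the qualitative structure the statistics are designed to detect:
a strongly bimodal ESR1 with ~70% of tumors in the high mode; an
ESR1-high/PGR-low population concentrated in LumB (dropout, not noise, so
ground truth can label it exactly); CA12 with two drivers, moderate noise
and no dropout (hence its higher fidelity to ESR1); TFF1 noisier than
GREB1. No attempt is made to match real marginal distributions
gene-by-gene.

True marker classes are defined on the noiseless drive: a sample is
true-ER-high when β + w·(its activities) exceeds the midpoint between the
smallest and largest subtype-expected drives for that gene (the mApo GATA3
mixture contributes both components to that range). Clinical ER/PR
statuses are the true classes flipped independently with probabilities
0.054 and 0.134 — the discordance levels reported for clinical-status
calls at transcriptome scale. Note that observed RNA-vs-status discordance
for PGR exceeds the flip rate, because dropout tumors are RNA-low while
their activity-derived class is high; this compounding is intentional and
is why PR looks worse than its nominal flip rate. HER2 status is positive
for a configurable fraction of mApo (0.7) and Basal (0.1) tumors.

All draws consume a single `numpy` Generator in a fixed order (subtype,
ER activity, mApo GATA3 component, GATA3 activity, per-gene noise and
dropout in sorted gene order, ER flips, PR flips, HER2), so a
`CohortParams` value identifies a cohort bit-for-bit.

### Simulated TMA scores

Each marker maps to a gene (ER→ESR1, CAXII→CA12, GATA3→GATA3,
FOXA1→FOXA1); three cores per tumor are drawn by default. The calibration
from expression to (proportion positive, intensity) is a clipped linear
ramp over the central 80% of the observed expression range, with Gaussian
noise (sd 0.05 on proportion, 0.15 on intensity) added before clipping. A
ramp rather than a sigmoid keeps the map exactly saturating: expression at
the floor yields exactly (0, 0) and at the ceiling (1, 3). The simulated
scores inherit the expression bimodality; they do not model staining
artifacts, intratumoral heterogeneity across cores beyond i.i.d. noise, or
pathologist rescoring — so IHC-arm tests validate the scoring arithmetic
and calibration logic, not robustness to real staining variability.

## Mixture thresholding

`fit_two_component_mixture` runs univariate two-component Gaussian EM with
two starts: a deterministic median split, and one random restart (two
distinct observations as means) drawn from the seed; the higher final
likelihood wins, making fits reproducible. Component variances are floored
at 10⁻⁶ of the total variance to prevent collapse. Convergence is a
log-likelihood increment below `tol` (default 1e-8) within `max_iter`
(500); the per-iteration log-likelihood trace is retained and is
non-decreasing by construction of EM.

Model selection compares BIC of the two-component fit (5 parameters)
against a single Gaussian (2 parameters); BIC's stronger penalty (vs AIC)
avoids spurious splits on unimodal decoy genes. The threshold is the
equal-posterior point between the means — the root of the quadratic
w₁φ(x|μ₁,σ₁) = w₂φ(x|μ₂,σ₂) lying between them, with a grid fallback when
no analytic root does. A threshold is reported only when EM converged
*and* BIC prefers two components; otherwise classification raises,
directing callers to treat the marker as unimodal.

Continuous expression classification uses value > threshold (ties → low:
conservative for positivity). IHC score positivity instead uses
score ≥ cut-off, matching the clinical convention for scores at the
cut-off; the two conventions are deliberate and documented side by side.

`trough_cutoff_from_scores` estimates the score density with a Gaussian
KDE (Silverman bandwidth by default) on [0, 8], takes the deepest local
minimum between the two highest local maxima, and rounds it *up* to the
score increment (default 0.5). Unimodal densities raise, directing users
to a fixed cut-off.

## Exclusion at fixed reference specificity

The cut-off is the smallest *observed* candidate value t with
F̂<sub>low</sub>(t) ≥ q — the ⌈q·n_low⌉-th order statistic of the
reference-low group, not an interpolated quantile — and "excluded" means
value ≤ t. This makes the statistic exactly reproducible by a brute-force
scan over observed values (a property the test suite enforces on random
instances, including heavily tied integer data) and invariant under any
strictly increasing transform of the candidate. Both normalisations of
the excluded-high count (fraction of the high group, fraction of all
samples) are reported, since summaries in the field use both denominators.

In the rescue analysis, alternative genes are classed by their own
q-specificity cut-offs (the same box construction as the primary
candidate), not by per-gene mixture fits — the comparison is between
thresholding rules of identical specificity. The reference low/high class
comes from the mixture fit, keeping the RNA arm self-contained; the CLI
accepts a clinical table only for the discordance columns.

## Enrichment and multiplicity

Subtype enrichment of a selection uses the one-sided upper-tail exact
hypergeometric P(X ≥ k | N, K, n); depletion appears as fold enrichment
< 1 without a second test. Q-values are Benjamini–Hochberg across the
labels of one selection. (BH is not idempotent on arbitrary adjusted
vectors — only constant q-vectors and similar fixed points re-adjust to
themselves; the tests check the fixed-point cases.)

## IHC analysis

Composite score = Allred-style proportion bin + continuous intensity.
Bin edges (0; (0,1%); [1%,10%); [10%,⅓); [⅓,⅔); ≥⅔ → bins 0–5) follow the
standard clinical proportion scale and are overridable; intensity stays
continuous in [0, 3] because image-analysis pipelines emit mean
intensities. Replicate cores are aggregated on the raw (proportion,
intensity) scale *before* binning (default mean; median/max available) —
binning after averaging avoids quantization noise.

Group comparisons: Kruskal–Wallis H with tie correction (scipy), then
Dunn's pairwise z = (R̄ᵢ−R̄ⱼ)/√((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ))
with Bonferroni adjustment over all pairs by default (Holm by option).
Inter-marker agreement is OLS of one marker's totals on another's; R²
equals the squared Pearson correlation to numerical precision, asserted
at 1e-10.

## Problem sizes and determinism

Validation runs use cohorts of n = 750–10,000 and 50–100 seeded
replicates per property — large enough that binomial 3-standard-error
bands around configured rates are tight, small enough that the whole
suite completes in well under a minute. The acceptance script uses
n = 754, a typical single-cohort transcriptome size. Every stochastic
entry point takes an explicit seed; there is no hidden global RNG state.

## Known limitations

* The generator's linear-Gaussian readout has no copy-number, methylation
  or survival structure, no LumC/Normal-like classes (LumC merges into
  LumA), and produces ER−PR+ tumors only through status flips — no
  mechanistic PR-autonomous state (configurable in principle via gene
  models, off by default).
* The exclusion statistic depends on the reference classification; with a
  poorly separated reference mixture the thresholds inherit that
  uncertainty, and no standard errors are attached to the reported
  fractions.
* Trough cut-off detection assumes a genuinely bimodal score histogram;
  heavily skewed but unimodal distributions are rejected rather than
  guessed at.
* The rescue union fraction treats alternatives symmetrically; it does not
  model correlation between alternative surrogates beyond what the data
  induce.
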