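# Methods

This note records the statistical conventions, numerical choices and known
limitations of `mrchain`. Everything stated here is computed by the test
suite or the example scripts; nothing is quoted from external runs.

## Instrument selection

Four filters run in a fixed order: p-threshold → LD clump → F-statistic →
confounder blacklist. Defaults: P < 1×10⁻⁵ (the usual relaxed cutoff when
genome-wide significance leaves too few instruments for molecular traits),
10,000 kb clumping window (center-to-center, inclusive), r² ≤ 0.001, F ≥ 10.

Clumping is greedy: SNPs are visited by ascending p (ties broken by
chromosome, position, id for determinism) and accepted iff no
already-accepted same-chromosome SNP within the window exceeds the r²
ceiling. Pairs absent from the LD table count as r² = 0 across chromosomes
or beyond the window, but as *unknown* inside it, in which case the less
significant SNP is dropped — without a reference panel the conservative
default is to assume the worst. Whether the F filter precedes or follows
clumping is not standardized in practice; here it follows clumping, and the
provenance log records which rule removed every excluded SNP. The per-SNP
F = (β̂/σ̂)² is the summary-data approximation (the squared Wald z); an
opt-in variance-explained form (n−2)·R²/(1−R²) with R² = 2·EAF·(1−EAF)·β²
is available when EAF and n are present.

Greedy clumping is not strictly monotone under arbitrary pairwise r²
structures (a newly admitted SNP can evict two others), so the
"relaxing thresholds never shrinks the set" property is guaranteed — and
tested — for block-structured LD, which is what real genomes and the
synthetic generator produce.

## Harmonization

Outcome records are mapped onto the exposure's allele pair: label match →
aligned; reversed labels → beta negated, EAF complemented; complementary
labels → strand flip (composed with a swap when also reversed). Palindromic
(A/T, C/G) SNPs are kept only when both EAFs are known and both fall on the
same extreme side of the spectrum (both < 0.42 or both > 0.58, the
conventional intermediate-frequency cutoff); any missing EAF, intermediate
frequency, or discordant extremes drops the SNP rather than guessing strand.
This is deliberately more conservative than tools that strand-correct
discordant extreme frequencies. No proxy lookup is attempted for SNPs absent
from the outcome; they are dropped and counted.

## Estimators

- **IVW**: closed-form weighted regression through the origin, weights
  1/σᵧ². Default is multiplicative random effects: the SE is inflated by
  √max(1, Q/(n−1)), so between-SNP heterogeneity can widen but never narrow
  the interval; with one SNP, IVW is exactly the Wald ratio.
- **MR-Egger**: closed-form WLS with intercept after orienting all exposure
  effects non-negative (the slope and weighted residual sum are
  orientation-invariant; the convention just fixes the intercept's sign).
  Residual scale uses √max(1, Q/(n−2)); slope and intercept p-values use t
  with n−2 df, reflecting the small instrument counts typical of these
  analyses. The scale floor means that even an exactly-fitting line keeps a
  finite intercept SE — significance on a purely deterministic fixture
  therefore needs a reasonably sized panel.
- **Weighted median**: ratios ordered, weights γ̂ₓ²/σᵧ² (the first-order
  inverse variance of the ratio) normalized; the estimate interpolates
  linearly in the midpoint cumulative weights at 0.5. SE by seeded parametric
  bootstrap (default 1000 resamples of both γ̂ₓ and γ̂ᵧ), since no usable
  closed form exists.
- **Modes**: Gaussian-kernel density of the ratios with bandwidth
  φ · 0.9 · min(sd, 1.4826·MAD) · n^(−1/5) (modified Silverman, φ = 1 by
  default), evaluated on a 512-point grid spanning the ratios ± 3 bandwidths;
  the simple variant weighs ratios equally, the weighted variant by
  γ̂ₓ²/σᵧ². Zero bandwidth (all ratios identical) returns the common ratio.
  SE by seeded parametric bootstrap with the bandwidth recomputed per
  resample.
- **Wald ratio**: first-order SE |σᵧ/γ̂ₓ| by default; a second-order option
  adds the γ̂ᵧ²σₓ²/γ̂ₓ⁴ delta term and reduces to the first-order form as
  σₓ → 0.

All reported 95% intervals use ±1.96·SE on the beta scale and exponentiate
to OR intervals, so `or_low = exp(ci_low)` always holds. P-values are
two-sided normal except the Egger slope/intercept (t, n−2 df). Exposure
units are passed through: if the exposure GWAS is per SD, estimates are per
SD; no re-standardization is attempted.

## Diagnostics

Cochran's Q is the weighted residual sum of the *fixed-effect* IVW fit
(df = n−1); Rücker's Q the same under the Egger fit (df = n−2); both are
referred to chi-square. Since the Egger model nests the origin-constrained
one, Q_egger ≤ Q_ivw always. Leave-one-out refits use the same IVW mode as
the headline fit.

The pleiotropy outlier test follows the residual-sum-of-squares simulation
recipe: per-SNP expected outcome effects come from the IVW fit that leaves
that SNP out; the observed weighted RSS is compared against parametric
simulations under the no-pleiotropy model (γ̂ₓ* ~ N(γ̂ₓ, σₓ),
γ̂ᵧ* ~ N(β̂₋ⱼγ̂ₓⱼ, σᵧ)); defaults are 1000 simulations and outlier level
0.05 with a Bonferroni-style per-SNP cutoff α/n. All empirical p-values use
the add-one rule and are bounded below by 1/(n_sim+1); with 1000 simulations
the per-SNP floor 1/1001 sits just under the 0.05/50 cutoff, so panels much
larger than ~50 SNPs need more simulations for the outlier test to be able
to fire. The distortion test compares the shift in the IVW estimate after
removing flagged outliers with shifts from removing equally many random
SNPs. The specific weighting and distortion conventions are this package's
own (the original tool's are not fully published); empirical p-values from
this block are therefore comparable in spirit, not digit-for-digit, with
other implementations.

## Screen gates and mediation

An exposure is retained when: IVW p < α (default 0.05, configurable; no
multiple-testing correction by default, mirroring common MR-screen practice —
an optional Benjamini-Hochberg flag exists and is off by default, a
documented limitation); all five methods agree in strict sign (zero counts
as inconsistent); both Q p-values, the Egger intercept p and the global
outlier p exceed 0.05. Gates are evaluated in that order and the first
failure is recorded. Diagnostics that the SNP count cannot support (Egger
terms below 3 SNPs, outlier test below 4) do not gate.

Mediation uses IVW point estimates for all three legs (the robust methods
are computed alongside for the direction-consistency check only). The
decomposition identities direct + indirect = β and R·β = indirect hold to
machine precision by construction; R is reported signed and unclipped, with
a flag when outside [0, 1] (inconsistent mediation). The indirect-effect SE
is the product delta method √(β₁²se₂² + β₂²se₁²) — an extension beyond the
published decomposition, which reports no uncertainty. The reverse screen
(outcome as exposure) requires all five methods' p > 0.05, strictly; when
the outcome GWAS yields too few instruments to run it — the norm for a rare
binary outcome at desk scale — the verdict is recorded as
`insufficient_instruments` and does not invalidate the result, it simply
could not be tested.

## Synthetic data

The generator emulates the data situation the package targets: a
quantitative exposure GWAS (default n = 3,757), a quantitative mediator GWAS
(n = 8,299), and a rare binary outcome GWAS (n = 20,000 at prevalence 0.003)
from three independent cohorts, with a handful of suggestive instruments per
molecular trait (default 25 causal SNPs at h² = 0.15 each for exposure and
mediator). Genotypes are Binomial(2, MAF) with MAF ~ U(0.05, 0.5);
independent loci are spaced beyond the clump window (12 Mb), while optional
LD blocks place tightly spaced SNPs that copy the anchor's alleles with a
set probability. The exposure and mediator have *disjoint* causal SNP sets —
real metabolites carry their own QTLs, and without them every
mediator-instrument would act on the outcome through the exposure's direct
effect, confounding the mediator→outcome leg by construction. Traits have
exact unit population variance (residual noise is solved analytically), so
the configured effects are the truth on the standardized scale; the outcome
intercept is solved numerically to hit the requested prevalence. Pleiotropy
is modelled as direct SNP→outcome offsets on a configurable fraction of the
exposure instruments.

Summary statistics come from per-SNP simple linear regression (quantitative)
or per-SNP logistic regression via vectorized Newton-Raphson (binary;
cross-checked against statsmodels in the tests), so binary-outcome betas are
genuine log-odds. A linear-probability option exists for speed in property
tests. A summary-level generator (`simulate_summary_effects`) draws
harmonized effect pairs directly from the two-sample model and powers the
calibration and power studies cheaply.

What the generator does **not** emulate: realistic LD maps and allele
frequencies, sample overlap, population stratification, imputation error,
assortative mating. Passing tests therefore demonstrate the correctness of
the statistical machinery under the model's own assumptions, not robustness
to those real-data complications.

## Validation scenarios and problem sizes

- **Parameter recovery**: 100 independent studies with three cohorts of
  5,000, 50 instruments each for exposure and mediator at h² = 0.6, chain
  effects (0.3, 0.4, 0.1), outcome prevalence 0.10. Each IVW leg must land
  within 3 SE of truth in ≥ 95% of studies, as must the indirect effect
  (delta-method SE) and the proportion mediated (ratio delta). The strong-
  instrument setting matters: weak instruments show the textbook regression-
  dilution attenuation of roughly h²/(h² + Σσₓ²), and a dedicated test
  confirms the attenuation shrinks between h² = 0.2 and h² = 0.6. The 10%
  prevalence is a desk-scale choice: at the emulated 0.3% prevalence a
  5,000-person cohort holds ~15 cases and per-SNP logistic fits are not
  stable.
- **Type-I error**: 500 null studies (n = 2,000 per cohort, 60 SNPs, 15
  known valid instruments used directly, prevalence 0.10); IVW rejection at
  α = 0.05 must fall in the exact binomial 95% band. The multiplicative
  random-effects floor makes IVW mildly conservative (~4%), which the band
  accommodates.
- **Egger calibration/power**: summary-level, 50 instruments; balanced
  pleiotropy (mean 0, sd 0.03) must reject at ~5%; directional pleiotropy
  (mean 0.03) must reject in > 50% of runs.
- **Estimator oracles**: IVW/Egger agree with an independent
  scaled-least-squares route to 1e-8 on random instances (and with
  statsmodels WLS); the weighted median agrees with a brute-force
  cumulative-weight interpolation to 1e-12.

## Known limitations

- No proxy-SNP search, no reference-panel LD computation, no VCF/GWAS-VCF
  ingestion (tab-delimited text only), no multi-allelic variants or indels.
- No MR-RAPS, contamination mixture, multivariable MR, Steiger filtering, or
  radial MR.
- Mediation treats a single mediator at a time; multiple mediators are
  decomposed independently, not jointly.
- The default screen applies no multiple-testing correction across
  exposures; large panels will admit chance findings at α = 0.05 unless the
  FDR flag or a stricter α is used.
- Bootstrap SEs (median, modes) are simulation-based and carry Monte-Carlo
  noise of order se/√(2·n_boot); seeds make them reproducible, not exact.
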