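# Methods

## The evidence-evaluation problem

Given two recordings — *reference* material of known origin and
*questioned* material of disputed origin — forensic voice comparison asks
how much more probable the measured acoustic evidence is if both
recordings come from the same speaker than if they come from two
different speakers drawn from the relevant population.  `phonlr`
evaluates this likelihood ratio (LR) per acoustic-phonetic parameter on
token tables (one row per measured speech unit), then calibrates, fuses
and validates the resulting score streams.

## Two-level kernel-density model

Tokens of speaker *i* are modeled as Gaussian around a speaker mean
θᵢ with shared within-speaker covariance **U**; the population of
speaker means is modeled non-parametrically as an equal-weight mixture
of Gaussian kernels placed at the background speakers' observed means,

g(θ) = (1/m) Σᵢ N(θ; x̄ᵢ, h²**C**),

with **C** the between-speaker covariance and the bandwidth
h = (4 / ((2p+1) m))^(1/(p+4)) for p dimensions and m background
speakers.  Estimates:

* **U** = pooled within-speaker scatter / Σ(nᵢ − 1);
* **C** = covariance of speaker means (n−1 denominator) minus **U**/ñ,
  where ñ is the harmonic mean of the per-speaker token counts (the
  background data are imbalanced before downsampling); the subtraction
  can make **C** indefinite at small m, so eigenvalues are floored at
  10⁻¹⁰·tr(**C**)/p;
* a relative ridge 10⁻⁸·tr(**U**)/p is added when **U** is
  near-singular (degenerate inputs fail soft with a warning).

Scoring uses the per-set sufficient means ȳₛ (n₁ tokens) and ȳ_q (n₂
tokens) with **U** fixed at the background estimate, so the LR

LR = ∫N(ȳₛ;θ,U/n₁)N(ȳ_q;θ,U/n₂)g(θ)dθ ÷
[∫N(ȳₛ;θ,U/n₁)g(θ)dθ · ∫N(ȳ_q;θ,U/n₂)g(θ)dθ]

has an exact closed form by Gaussian-product algebra.  All likelihood
algebra is done in natural-log space; reported scores are log₁₀ LR.
The closed form is verified against an independent adaptive-quadrature
oracle (`numeric_lr_oracle`, p ≤ 2) to better than 10⁻⁶ on the
natural-log scale, and is affine-invariant to 10⁻⁸ by construction
(covariances and means transform consistently).

## Calibration and fusion

Raw scores are mapped to calibrated log-LRs by an affine transform
fitted by logistic regression on the same trials ("self-calibration",
the design used with downsampling replications; a held-out variant is a
one-line change since the trial set is explicit).  The objective is the
class-balanced cross-entropy at effective target prior 0.5 — balancing
matters because different-speaker trials (all unordered pairs, e.g. 190
for 20 speakers) vastly outnumber same-speaker trials (one per speaker)
— plus an L2 ridge (default 10⁻³) on the weights only, which keeps the
fit finite on separable score sets.  Fusion of several systems is the
same fit with one weight per input stream.  Weights are unconstrained in
sign; negative weights are logged as a calibration warning.  Because the
multi-system feasible set contains every single-system solution, a fused
system's training Cllr can exceed its best component's by at most the
ridge slack.

## Validity metrics

* **Cllr** = ½[mean_same log₂(1 + 1/LR) + mean_diff log₂(1 + LR)]:
  0 = perfect, 1 = uninformative; computed on calibrated LRs by default.
* **EER**: thresholds swept at midpoints between adjacent distinct
  scores; a trial is accepted when score ≥ τ; FRR(τ) = fraction of
  same-speaker scores < τ, FAR(τ) = fraction of different-speaker scores
  ≥ τ; the FAR/FRR crossing is located by linear interpolation.  This
  reproduces an exhaustive-threshold sweep exactly and is invariant to
  monotone transforms of the scores.  The implementation reports the
  crossing value as-is (it does not emulate conventions that can print
  EER above 0.5).

## Conditions and trial construction

Matched conditions (`dialogue`, `interview`): different-speaker trials
compare the full token sets of every unordered speaker pair;
same-speaker trials split each speaker's tokens into two disjoint random
halves (re-randomized every replication, so split noise enters the
replication envelope the way selection bias does).  The mismatched
condition (`dialogue_vs_interview`) uses interview material as reference
and dialogue material as questioned, for both trial kinds.  For every
trial the background is refitted on all speakers except the one(s)
compared, using reference-style tokens (the natural choice when the
reference side defines the known-origin population; the source protocol
does not state which style the background uses).  Parameter combinations
are fusions of per-parameter score streams; a joint multivariate mode
exists for parameters measured on the same unit (e.g. F1+F2+F3).
Grouping vowels by quality (score per quality, fuse across qualities) is
available but off by default for synthetic data, which does not model
phoneme identity.

## Balanced downsampling and replication

Every speaker is downsampled without replacement to the smallest
per-speaker count ("minority case") of the unit type at hand, separately
per speaking style; in the mismatched condition the minimum is taken
across both styles so the number of observations per style is constant.
Because selection is random the experiment is replicated (R = 200 in the
reference protocol; R = 20 in the desk-scale sweeps used by the tests
and acceptance script) with seeds base_seed + replication index, and
metrics are reported as Average / Median / Minima / Maxima / SD
(arithmetic mean; sample SD).

## Synthetic generator

The generator emulates the statistical skeleton of a 20-speaker,
two-style conversational corpus: two-level Gaussian features (speaker
means drawn once; tokens around them), durations log-normal, per-speaker
token counts imbalanced with the low endpoint of each per-style range
equal to the study-scale minority count (432/393/22 dialogue and
262/362/30 interview vowels/V-V units/pauses per speaker) and one random
speaker pinned to that minimum — so balanced totals are exactly
8,640/7,860/440 and 5,240/7,240/600.  Dialogue differs from interview by
an additive mean shift δ and a within-SD inflation κ per feature (κ=1.1
temporal, 1.4 otherwise), the mechanism behind mismatch degradation.
Generated silent pauses respect the 100 ms annotation threshold
(sub-threshold pauses do not occur in segmented corpora); f0 summaries
are generated in semitones re 1 Hz, and a separate raw-sample generator
produces per-chunk f0 vectors inside the 60–300 Hz extraction range for
testing the summary pipeline (median and 7.64th-percentile base value).

Population means and SDs are invented but plausible for adult male
Brazilian Portuguese speech (f0 median ≈ 120 Hz, F1–F4 ≈ 500/1500/2550/
3700 Hz, vowels ≈ 80 ms, interview pauses ≈ 800 ms; δ = 1.6 within-SD
for temporal features and 1.2 within-SD otherwise).  The knob that
matters downstream is the between/within variance ratio per feature,
ordered spectral (F3, F4 strongest) > melodic > temporal.  Magnitudes
were chosen so that, under this iid two-level model and the token counts
used here, the per-class Cllr medians come out clearly ordered
(temporal weakest at roughly 0.5–0.9, melodic 0.3–0.55, spectral
0.15–0.4 in matched conditions) with the ordering stable across
generator seeds.  The ratios are deliberately smaller than raw acoustic
surveys would suggest: iid tokens are individually more informative than
real, serially correlated speech tokens, so matching raw survey SDs
would make every parameter near-perfect at realistic token counts.
The silent-pause ratio is set high enough (between ≈ within on the log
scale) that the parameter stays away from the chance line, where EER
comparisons between conditions stop being meaningful; as a result the
pause parameter here is not the single weakest system, a nuance of real
conversational data this generator does not reproduce (the same applies
to F2, which real data rank below the melodic parameters).
Within-class correlation defaults: 0.7 between the two f0 summaries,
0.5 among formants, 0.3 among durations; 0.2 across classes — this is
what gives multi-class fusion its edge (orthogonal information) while
keeping same-class fusion gains modest.

**What passing tests do and do not show.**  The generator satisfies the
scoring model's assumptions exactly, so results here validate the
machinery (estimation, scoring, calibration, metrics, resampling) and
the qualitative effect structure, not field performance: real speech has
session effects, serial correlation within chunks, phoneme-dependent
formants, and non-Gaussian tails, all of which reduce the effective
information per token in ways the iid model does not capture.

## Problem sizes and numerical choices

Replication sweeps run at 10 speakers × 60 tokens per unit per style
with R = 20, which keeps a three-condition, nine-parameter sweep at a
few minutes on one core while leaving the qualitative effects clearly
resolved; the downsampling-arithmetic check runs at the full 20-speaker
study scale.  Optimization of the calibration objective uses L-BFGS with
analytic gradients from a zero start (the objective is convex; gradient
tolerance 10⁻¹⁰).  Quadrature oracles integrate the shifted integrand
with breakpoints at all density peaks.  Ties in the EER sweep follow the
accept-at-≥τ convention.  Same-speaker half-splits use floor(n/2)
reference tokens and the remainder as questioned.

## Known limitations

* Self-calibration slightly underestimates Cllr relative to
  cross-validated calibration; with ≥ 55 trials per fit the difference
  is within the ridge slack (~0.02).
* EER on small speaker sets is quantized (1/n_same resolution per
  replication); aggregates over replications smooth this.
* The closed-form scorer conditions on **U** (no uncertainty propagated
  from its estimation), standard for this model family.
* No audio processing: the package starts from token tables; pitch
  tracking, formant estimation and segmentation live upstream.
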