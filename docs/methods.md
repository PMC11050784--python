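# Methods

This note describes the statistical machinery implemented in `jolreact`,
the choices made where several defensible conventions exist, and what the
synthetic-data generator does and does not emulate.

## Design and data model

The package analyzes a two-condition within-subject word-list learning
design: on half of the study lists participants make a judgment of
learning (JOL) for each word, on the other half they perform a matched
key-press task (no-JOL). Memory is probed with an old/new recognition
test on a 4-point confidence scale (1 = definitely new … 4 = definitely
old). EEG is epoched around the onset of the first word presentation,
−1000 to +2000 ms at 500 Hz, 40 analysis channels.

Conventions fixed throughout:

* time in ms relative to stimulus onset; sample *k* of an epoch lies at
  `t_start + k·1000/sfreq`; window selection `[t_lo, t_hi]` is
  endpoint-inclusive, so 0–300 ms at 500 Hz selects 151 samples and
  300–1400 ms selects 551;
* potentials in µV, TSE in percent, electrode coordinates in mm;
* condition coding for regression models: JOL = 0, no-JOL = 1. With this
  coding a *negative* condition coefficient means the JOL condition has
  the larger value.

## Recognition scoring (signal detection)

Responses 3–4 are "old" judgments: hits on old items, false alarms on
new items. New items are studied in neither condition, so each subject's
single false-alarm rate is shared by both conditions' scores. With the
equal-variance Gaussian model,

    d′ = z(H) − z(F),   c = −(z(H) + z(F))/2,   c′ = c / d′,

where `z` is the inverse normal CDF. Extreme proportions are protected
by the half-count rule (0 → 1/(2N), 1 → 1 − 1/(2N)); a log-linear
alternative ((count + 0.5)/(N + 1), applied to every rate) is available
via the `correction` argument. c′ is undefined (NaN) at d′ = 0; both c
and c′ are reported.

Group inference on d′ uses the paired t-test with Cohen's
d = t/√n and a two-sided 95% CI. The Bayes factor is the default-prior
(JZS) BF₁₀: the marginal likelihood of t under a Cauchy(0, √2/2) prior
on the standardized effect size, relative to the central-t null, by
adaptive quadrature (relative tolerance 1e-8, verified against an
independent implementation and a brute-force trapezoid oracle). A
one-sided (half-Cauchy) variant is available. Power analysis uses the
exact noncentral-t distribution of the paired test (noncentrality d·√n,
df = n − 1), not a normal approximation; `required_n` inverts it by
bisection.

Known discrepancy: for the group contrast t = 8.031 with n = 27 the
package computes BF₁₀ = 8.12×10⁵ (two-sided) or 1.62×10⁶ (one-sided).
The value sometimes quoted for this contrast, 2.475×10⁶, cannot be
reproduced from these inputs under any standard scale or sidedness of
the JZS prior; the two-sided t that would yield it is ≈ 8.55. The
package reports what the integral gives.

## ERP cluster permutation test

Per subject and condition, trials are averaged and baseline-corrected
(−300..0 ms). The paired contrast JOL − no-JOL is tested pointwise
(one-tailed-right) over every (electrode, time point) in the search
window — 0–300 ms for the P200 analysis, 300–1400 ms for the LPC
analysis. Supra-threshold points (p < 0.05) are clustered under the
connectivity rule *same electrode + adjacent samples OR same sample +
adjacent electrodes*; diagonal space-time adjacency is excluded.
Electrode adjacency is Euclidean distance ≤ 45 mm on the montage.
The cluster statistic is the sum of member t-values.

The permutation null swaps each subject's condition labels
independently — equivalently sign-flips that subject's difference wave —
and keeps the largest cluster sum per permutation (5000 by default).
Because per-subject sign flips leave the pointwise sum of squares
invariant, permuted t-maps are computed from the flipped means alone,
which makes the permutation loop cheap. Cluster p-values use the
positively biased estimator p = (1 + #{null ≥ observed})/(1 + n_perm),
which can never return 0. Zero-variance points get t = 0 and never
enter clusters. Permutations warn below 100 iterations and when no seed
is given.

The mediator amplitude of a significant cluster averages the evoked
response over the cluster's significant electrodes × its full time
window (a rectangular region); averaging over the exact cluster mask is
available via `use_mask=True`. The rectangle is the default because the
mediator is defined as "the average ERP of the cluster's significant
electrodes" over the cluster window.

## Electrode montage

No electrode-position file accompanies the design, so the package ships
`standard40.sfp`: the 40 analysis labels at standard 10-10 template
angular positions, radially projected onto an 85 mm sphere. Under the
45 mm rule this montage yields a mean of 5.35 neighbors per electrode
(the reference analysis reports 5.15 with its proprietary coordinate
file; the difference is montage-file approximation). A naive
equal-angular-spacing spherical construction was rejected — it packs
electrodes too densely (7.2 mean neighbors).

## Time–frequency analysis (complex demodulation, TSE)

Phase-locked activity is removed first: each trial minus its own
condition's mean waveform, so residual trial means are exactly zero and
the spectral measures reflect induced activity only.

Band power at frequency f is extracted by complex demodulation:
multiply by `exp(−i2πft)`, low-pass with a Gaussian FIR kernel, and take
P = |2y|², so a stationary sinusoid of amplitude A yields P = A². The
kernel's squared-magnitude impulse response has FWHM 78.8 ms
(amplitude-domain σ = FWHM/(2√ln2) ≈ 47.3 ms), truncated at ±3σ and
renormalized to unit sum; edge samples divide by the kernel mass that
falls inside the epoch. The stated time/frequency resolution pair
(78.8 ms and 1.42 Hz power FWHM) is not jointly attainable by a single
Gaussian filter (their product is far below the Gaussian uncertainty
bound), so the two are implemented as separable smoothings: the temporal
kernel above per frequency, plus a Gaussian smoothing of power across
the 1 Hz frequency grid with power FWHM 1.42 Hz. Both are independently
configurable. A consequence of the 78.8 ms temporal kernel is a
spectral power FWHM of ≈5.6 Hz per frequency bin: narrow-band
components leak several Hz, and the test suite checks tone
superposition at 15 Hz separation where leakage is <1% (at 10 Hz
separation it is ≈2%).

Demodulation shares one forward FFT across all analysis frequencies via
`conv(x·e_f, k) = e_f(t)·conv(x, k·e_f*)`, which makes the 29-frequency
transform affordable on a single core.

Trial-averaged power is averaged into 50 ms × 1 Hz bins labelled by bin
start time (60 bins covering the epoch; the 0–1400 ms analysis range
spans 29 bins, 2–30 Hz spans 29 frequencies). The temporal spectral
evolution is TSE(t, f) = 100·(P(t, f) − P_b(f))/P_b(f) with P_b the mean
power over baseline bins (bins fully inside −300..0 ms). Negative TSE
is event-related desynchronization (ERD). Power is averaged across
trials per condition *before* baseline normalization. TSE is invariant
to rescaling the raw signals; an amplitude drop to ratio r appears as
TSE = 100·(r² − 1) (r = 0.5 → −75%).

## Two-step time–frequency cluster test

Step 1 is non-spatial: TSE maps are averaged across all electrodes,
and each 50 ms × 1 Hz bin in 0–1400 ms × 2–30 Hz is tested with a
one-tailed-left paired t (power decreases under JOL). Supra-threshold
bins are clustered by 4-connectivity on the bin grid (no diagonals),
the statistic is again the t-sum, and the max-cluster permutation null
uses the same per-subject condition swaps.

Step 2 takes each significant cluster's bounding box — its maximum time
range × maximum frequency range — averages per-electrode TSE over that
rectangle, and reports one paired t per electrode with *uncorrected*
p-values and a 0.05 significance flag. No second cluster correction is
applied, to avoid circular inference on bins already selected in step 1.
The band-power mediator for the mediation models averages TSE over the
significant electrodes × the bounding box.

## Multilevel mediation

The 1-1-1 mediation model tests whether an EEG signal (cluster ERP
amplitude or cluster band power) carries part of the condition effect on
d′. All three variables vary within subject, two observations per
subject. Path a comes from the mixed model `mediator ~ condition +
(1 | subject)`; paths b and c′ from `outcome ~ condition + mediator +
(1 | subject)` (statsmodels MixedLM, REML). With two observations per
subject random slopes are unidentifiable, so the models carry random
intercepts only. Mediator and outcome are grand-mean centered and, by
default, scaled to unit SD so coefficients are on the β scale; raw-scale
estimates are available.

The indirect effect a·b gets a Monte Carlo interval: `mc_samples`
(default 1000) independent draws a* ~ N(â, SEa), b* ~ N(b̂, SEb); CI
from the 2.5/97.5 percentiles of a*·b*, z = â·b̂/SD(a*·b*). The a–b
sampling covariance is taken as 0 (the two paths come from different
models). The direct effect's CI uses Monte Carlo draws of ĉ′ the same
way. Under the linear model total ≈ direct + indirect; small deviations
arise from multilevel shrinkage differences between the two fitted
models (the test suite allows 0.05 on standardized data).

## Synthetic-data generator

The generator emulates the study's statistical structure so every
pipeline stage can be exercised and recovery-tested without real data.
Defaults are the study's design constants: 27 subjects, 200 studied
words per condition (two 100-word lists), 400 old + 200 new recognition
trials, 40 channels, −1000..2000 ms epochs at 500 Hz.

Behavior: per subject, old-item strengths are Normal(d′, 1) and new-item
strengths Normal(0, 1); the 4-point response uses thresholds at
λ − 0.5, λ, λ + 0.5 with λ = mean-d′/2 + criterion, so recovered d′ is
unbiased at any criterion. Mean d′ is 1.400 (JOL) and 0.832 (no-JOL);
the between-subject SD of the no-JOL level is 0.60 and of the JOL
advantage ≈0.35, chosen to match the reported group SDs (0.73/0.64) and
the reported difference CI.

EEG: each trial is 1/f-shaped Gaussian noise (exponent 1, RMS 10 µV,
independent per channel) plus phase-locked Gaussian-envelope evoked
components — a fronto-central P200-like bump (peak FC3, center 205 ms,
FWHM 90 ms, 3.0 vs 1.8 µV) and a centro-parietal sustained LPC-like
deflection (peak CP1, center 705 ms, FWHM 560 ms, 4.0 vs 2.8 µV) — plus
induced oscillations with uniformly random phase per trial: alpha
(10 Hz, 5 µV, peak C3) dropping post-stimulus to amplitude ratio
0.5 vs 0.72 over 500–1450 ms, and beta (20 Hz, 2.5 µV, peak C4) to
0.6 vs 0.8 over 550–1400 ms, with 50 ms linear ramps to limit spectral
splatter. Random phase makes the induced components survive evoked
subtraction while the phase-locked components do not. The reference
analysis reports cluster statistics rather than µV effect sizes, so the
amplitudes are free parameters chosen for comfortable detection at
n = 27. Spatial maps are Gaussian in scalp distance around the peak
electrode.

Coupling: a latent per-subject engagement factor u ~ N(0,1) scales the
EEG condition effects (scale 1 + 0.40·u) and enters the behavioral JOL
advantage with weight `coupling` (default 0.25), so a true indirect
effect exists when coupling > 0 and vanishes at coupling = 0. The
generator records all latent values as ground truth.

What the generator does *not* emulate: spatially correlated noise
(channels are independent — the cluster test's validity rests on
exchangeability, not on noise covariance), realistic head-model forward
projection, artifacts, item-level JOL ratings, or trial-order effects.
Passing recovery tests therefore show that the pipeline detects effects
of the configured kind and size under clean exchangeable noise, not that
it is robust to every property of real EEG.

## Problem sizes used in the test suite

The full study conditions (27 subjects × 200 epochs/condition, 5000
permutations) are the package defaults. The test suite runs reduced
sizes chosen as the package's own verification budget: the end-to-end
recovery uses 40 EEG epochs per condition (emulating artifact-rejection
loss; the recognition test keeps its full 400/200 items) with 500–1000
permutations; the type-I-error study uses 200 pure-noise replicates of
12 subjects × 20 channels × 76 samples at 200 permutations; exhaustive
sign-flip enumeration oracles use n = 5 subjects (32 patterns).
Monte-Carlo mediation calibration uses 50 replicates of the
subject-level coupling model.

## Known limitations

* The BESA-style coupling of "time resolution" and "frequency
  resolution" is proprietary; the separable-smoothing reading here is an
  approximation and is flagged in output provenance.
* MixedLM variance components can hit the boundary (variance 0) with
  n = 27 and two observations per subject; estimates remain valid but
  their SEs are the usual asymptotic ones.
* One-tailed directions follow the design's predictions (ERP: right;
  ERD: left) and are configurable but not inferred from data.
* The two-sided cluster test merges adjacent positive and negative
  supra-threshold points into one component if they touch; the analyses
  here are one-tailed, where this cannot occur.
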