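# Methods

This note documents the models, estimators and numerical choices behind
`ne_awake`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Photometry preprocessing

The 405-nm isosbestic channel is insensitive to NE binding and shares the
signal channel's motion and photobleaching artifacts, so it serves as the
f₀ reference: per contiguous LED-on block the isosbestic trace is fitted
to the signal by ordinary least squares (`a·iso + b`) and
ΔF/F = (signal − fit)/fit × 100 %. Fitting per block (the default; a
whole-session mode is available) tracks bleaching that differs across
hour-long LED duty cycles. A constant isosbestic channel makes the fit
degenerate and is rejected; a non-positive fitted reference on valid
samples is an error naming the offending sample range. ΔF/F is invariant
to rescaling both channels by a common positive factor.

Epoching cuts per-trial windows (default −5 to +4 s), block-averages
consecutive samples by a factor of 10 (1017.25 → 101.725 Hz; the raw
signal is already low-pass shaped at 6 Hz, far below the decimated
Nyquist, so plain block averaging is alias-safe) and subtracts each
trial's mean over the baseline window (default −5..0 s). Trials whose
window leaves the recording or touches LED-off samples are dropped and
counted.

## Response-window detection

The cohort-level question is *when* after sound onset the NE signal is
reliably above baseline. Per mouse, the trial-averaged trace is reduced
to 13 bin means (0.3-s bins over 0–3.9 s; the bin count fixes the
correction family, and a partial trailing bin would be dropped with a log
entry). Detection is three-staged:

1. **Omnibus**: Kruskal–Wallis (midranks, tie-corrected) across the bins
   of per-mouse means. If not significant at α no windows are reported —
   this gate also keeps the family-wise false-window rate conservative.
2. **Many-to-one comparison against zero**: each bin's across-mouse values
   give a one-sample t statistic (df = n_mice − 1). Because the same mice
   contribute every bin, the statistics are correlated; the joint null is
   modeled as an equicorrelated multivariate t with correlation set to the
   mean off-diagonal bin correlation (the full 13 × 13 sample correlation
   is singular with 7 mice). Corrected p for bin k is P(max_j T_j ≥ t_k),
   evaluated either through the multivariate-t CDF (`method="mvt"`,
   quasi-Monte Carlo, seeded, floored at the single-comparison p to guard
   round-off) or by direct simulation of the max statistic
   (`method="mc"`), which doubles as the testing oracle. Corrected
   significance is always a subset of uncorrected significance.
3. **Grouping**: maximal runs of consecutive significant bins become
   windows carrying per-bin corrected p-values.

Calibration (see `ne_awake.calibration` and the acceptance suite): on
pure-noise cohorts the probability of reporting any window stays at or
below the nominal 5 %; with the generator's default surge (1 % ΔF/F over
0.3–0.6 s against 1 % per-sample noise, 7 mice × 40 trials) the exact
injected window is recovered in ≳90 % of cohorts. A uniform bump of
3 standard errors (across mice) is *not* reliably recovered under the
family correction at n = 7 — the correction costs roughly 1.5 SEM of
power — which is why the power analyses use the generator's configured
amplitudes rather than an SEM-scaled bump.

## Element scores and outcome models

Per trial, the window score is the mean ΔF/F inside a detected window and
the drop score the minimum within 2 s after the window's end (the
post-surge dip has no formally defined window; 2 s covers its reported
latency). Outcome contrasts use per-mouse means and a paired t test
(identical means give t = 0, p = 1 rather than an undefined statistic).
Pearson correlations are two-sided throughout; per-mouse correlations
require ≥3 trials and non-degenerate variance. The outcome model is a
multinomial (binomial for two classes) logistic regression fitted by
maximum likelihood, reported with per-feature Wald statistics and a
likelihood-ratio χ² against the intercept-only model,
df = n_features × (K − 1); complete separation is flagged and refitted
with a small L2 penalty. Cross-correlation is normalized by the full
length (biased), z-scored, with positive lag meaning the second trace
lags the first.

## EEG/EMG spectral analysis

The ERSP is a Hanning-tapered short-time FFT log-power map per trial
(default 2-s taper, capped at 10 s, 50 % overlap, 1–50 Hz), averaged over
trials *as log power* (no single-trial normalization) and normalized per
frequency by subtracting the mean log power over the pre-event baseline
(−30..0 s), giving dB = 10·log10. Amplitude doubling of a sinusoid reads
as +6.02 dB at its frequency. Because individual log-periodogram pixels
carry ~5.6 dB of chi-square noise per trial, "the null ERSP is zero" is
checked on map averages (whose SE follows from across-trial spread), not
per pixel. EMG tone is the RMS per 100-ms bin over −5..15 s, per-trial
baseline-subtracted, averaged over 0–4 s post onset.

Condition-vs-sham inference uses a paired t-map over per-mouse ERSP
differences, thresholded at the parametric one-sided critical value for
the cluster-forming α (0.1). Supra-threshold pixels are grouped by
4-connectivity on the (frequency, time) grid and scored by summed t
(cluster mass); neither the connectivity nor the mass statistic is
canonical, both are stated here as this package's choice. The null is the
maximum cluster mass over sign-flip permutations of the difference maps
(1000 by default), and cluster p = (1 + #{null ≥ observed})/(n_perm + 1),
bounded below by 1/(n_perm + 1). With 7 mice the sign-flip group has 128
distinct elements, so p-values are granular at ~0.008; calibration holds
at the 5 % level nonetheless. Post hoc comparisons of cluster mean power
across conditions use one-way ANOVA plus many-to-one comparisons against
the sham sample (Dunnett's test proper, which applies here because sham
is an observed control group — unlike the response-window stage, where
the reference is the constant zero).

## Anatomical distribution comparison

Counts live on an AP-slice × DV-strip grid (AP −5.34..−5.8 mm; nine
100-µm DV strips with lower edges −3.3..−4.1 mm, covering −3.2..−4.1 mm).
Histological yield differs per animal and slices are unevenly available,
so raw counts pass through a normalization chain: expected yield E(loc) =
mean count across animals with data at loc; animal yield A = the animal's
total; normal yield N = ΣE over the animal's available locations;
normalized gradient = count/(E·A/N); average distribution = E/ΣE. A
group's map is the group-mean normalized gradient × average distribution,
renormalized to unit mass. Missing slices are absent observations, never
zeros.

Two invariances matter. A single animal's *distribution* (its normalized
gradient × average distribution, renormalized) reduces algebraically to
its own count distribution, hence is exactly invariant to multiplicative
yield scaling. The intermediate normalized-gradient values are only
approximately scale-invariant, because the expected yield includes the
animal itself; tests therefore assert the exact form.

The group difference statistic is √(Σ w·(P₁ − P₂)²/Σ w) with w the
per-location fraction of animals (both groups pooled) with numeric data;
an unweighted variant is available by flag. The permutation test holds
group sizes fixed and randomizes the animal-to-group assignment,
one-tailed for the overall statistic (reject for large values), two-tailed
on |difference| for the DV/AP location statistics (distribution-weighted
mean coordinates). When the number of distinct assignments is ≤10,000 the
null is enumerated exactly (e.g. C(15,8) = 6435 for an 8-vs-7 cohort —
the calibration study uses this in place of sampled permutations, which
is the same inference with zero Monte Carlo error); otherwise Monte Carlo
with p = (1 + #{null ≥ obs})/(n_perm + 1), ties counted as exceeding.

Colocalization: per slice, BF ratio = colocalized/red (BF-tagged) and
PRN ratio = colocalized/green (PRN-tagged); zero-denominator slices are
skipped. Per-mouse mean ratios are tested against 1 — full overlap of one
subpopulation in the other — with a one-sample t, one-sided (ratio < 1).
The one-sample form is used because the hypothesis compares one group of
per-mouse ratios to a constant.

## Trial-outcome rules

The response window is 0–3 s after sound onset, with the baseline state
read 5 s before onset; unstable baselines are discarded. Full awakening
requires EEG activation, EMG activation and movement all present and
jointly persisting to ≥3 s after onset (the "lasted at least 3 s"
criterion is interpreted as persistence from the joint onset to the end
of the response window; the minimum duration is configurable); the same
conjunction ending earlier is a short awakening; no change anywhere is
maintained sleep; a single activated channel is tagged by that channel.
Two open corners are not covered by the written rules and are resolved
explicitly: two activated channels take the label of the
highest-precedence channel (EEG > EMG, with a warning), and movement-only
trials — visibly not maintained, yet not an EEG/EMG activation — are
discarded. Hypnograms are at fixed 1-s resolution; light/dark phase can
be used as an optional grouping key.

Transition curves: for each second 0..60 after onset, the fraction of
trials in each state, over trials whose state 5 s before onset matched
the base state; rows sum to 1 by construction. Window means over curves
use inclusive endpoints (a 5–10 s window averages six samples).

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical structure* the analyses rely
on: shared exponential photobleaching across channels (decaying to a 70 %
plateau), iid Gaussian noise low-pass shaped at the 6-Hz acquisition
corner, stimulus-locked components only on awakening-designated trials
(rectangular surge at 0.3–0.6 s; half-sine rise at 1.8–3 s), hourly LED
duty cycles as epoch masks, 60 ± 0.5 s trial spacing with 73/80/88 dB
intensities and per-intensity awakening rates of 27.9/34.4/38.2 %,
state-gated band-limited EEG components (delta and sigma up in NREM,
theta in REM) and state-scaled EMG tone over a semi-Markov hypnogram,
negative-binomial cell counts (dispersion 5) around separable Gaussian
(AP, DV) gradients with log-normal per-animal yield and whole-slice
missingness, and multinomial colocalization categories.

It does **not** emulate LC spiking, hemodynamics, pupil dynamics, real
EEG waveforms (spindle morphology, K-complexes), motion artifacts, or
sensor kinetics. Passing tests therefore demonstrate that the estimators
are correct and calibrated under the stated noise model — not that real
recordings satisfy that model. Amplitude defaults (1 % ΔF/F responses
against 1 % noise) put cohorts of 7 mice × 40 trials at ≳90 % recovery
power, a deliberate "clearly detectable" regime.

All randomness derives from one session seed through named
`SeedSequence` spawn keys (schedule, photometry, sleep, cell_counts,
colocalization, epoch_cohort, outcomes); fixed seed means bit-identical
output, including byte-identical HDF5 files (dataset timestamps are
disabled).

## Numerical choices and degenerate inputs

- Analysis span 0–3.9 s with 13 × 0.3-s bins: the stated bin count is
  honored over the nominal 4-s endpoint, since it fixes the multiple-
  comparison family; both are configurable.
- The late-rise window is representable as either 1.8–3 s or 1.8–3.9 s;
  neither is hard-coded.
- Equicorrelation estimates are clipped to [0, 0.95]; negative estimates
  collapse to 0, which is conservative for the max-statistic threshold.
- Kruskal–Wallis uses midranks with tie correction (scipy).
- Empty groups, all-missing animals, zero-variance covariates,
  zero-denominator slices and out-of-range trials are either rejected
  with named errors or excluded with log entries, as documented per
  function.
- Problem sizes in the calibration studies (500 anatomical null cohorts,
  100 recovery and 200 null detection cohorts, 200 cluster null sets at
  20 × 30 maps, 20 correction-oracle instances at 100,000 draws) were
  chosen to give binomial confidence bands tight enough to detect
  miscalibration of a 5 % test while keeping the full suite to a few
  minutes on one core.

## Known limitations

- The Dunnett-style correction assumes exchangeable (equicorrelated)
  bins; strongly structured autocorrelation beyond that is approximated.
- The cluster test's parametric cluster-forming threshold assumes
  approximate normality of per-mouse ERSP differences.
- The anatomical permutation test conditions on the observed missingness
  pattern; systematically group-dependent slice availability would not be
  distinguishable from a distribution difference.
- With two outcome classes the multinomial model is a plain logistic
  regression; per-mouse random effects are not modeled (the mouse id is
  retained for optional stratification).
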