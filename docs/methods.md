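# Methods

This note records the models behind `eegdx`, the defaults that matter, what
the synthetic cohorts do and do not emulate, and the numerical choices made
where the published descriptions of these methods leave the design open.

## Signal model and preprocessing

Recordings are 30-channel scalp EEG (modified 10–20 montage, common
reference) sampled at 256 Hz; the analysis unit is a 20-s artifact-free
segment per subject. Segments are band-pass filtered 1–30 Hz with a
3rd-order Butterworth design (three analog poles per edge), applied
forward–backward per channel, so the effective response is the squared
magnitude with zero phase. Zero-phase filtering was chosen so that bump
latencies are not shifted; a causal single-pass mode exists
(`zero_phase=False`) for streaming-like use. Band features re-filter the
raw segment directly at the band corners (delta 1–4, theta 4–8, alpha 8–12,
beta 12–30, broad 8–30 Hz) rather than cascading on the 1–30 Hz output; the
two orders differ only by the second filter's passband ripple and the
direct design is the simpler to reason about.

Region definitions (frontal = Fp1 Fp2 F7 F3 Fz F4 F8; occipital = O1 Oz
O2; temporal = FT7 T3 TP7 T5 FT8 T4 TP8 T6; frontal+occipital = union; all
= 30 channels) follow the standard 10–20 lobe assignment and can be
overridden from YAML (`eegdx.montage.load_region_map`) for other montages.

## Epoch-based entropy

A continuous left-to-right HMM with S states and M-component
Gaussian-mixture emissions (diagonal covariance) is fitted per subject to
the D-channel sample vectors (one observation per time sample, no windowed
features). States model quasi-stationary stretches; the Viterbi path cuts
the signal into N epochs (maximal constant-state runs), necessarily
time-ordered by the left-to-right topology.

Per epoch, the default entropy estimator is the Monte-Carlo differential
entropy of the epoch's emission density in bits,
H* = −mean(log₂ P_i(z)); the subject's EpEn is the mean over epochs. An
alternative "literal" estimator, −Σ_z P_i(z)·log₂ P_i(z) without
normalization by the epoch length, is kept behind
`EpEnConfig(estimator="literal")`: it treats the density values as if they
were probability masses, is not scale-consistent (its value changes
non-linearly when the signal is rescaled), and is provided for comparison
only. The MC default obeys two exact identities used as test oracles:
scaling data and model by c adds D·log₂ c bits, and a 1-state/1-mixture fit
on Gaussian data reproduces Σ_d ½·log₂(2πe·σ_d²).

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_states S | 3 | a 20-s resting segment rarely supports more distinct regimes |
| n_mix M | 4 | enough to capture non-Gaussian (e.g. rhythmic) sample densities |
| variance floor | 1e-3 µV² | keeps degenerate channels from collapsing the density |
| EM stop | rel. improvement < 1e-4 or 100 iterations | likelihood plateaus long before |
| init | per-state GMM on time-uniform blocks | left-to-right states are time segments; amplitude-clustering inits collapse the chain |

Fitting is hmmlearn's Baum–Welch with the transition matrix constrained
upper-bidiagonal (zeros are invariant under EM). Numerical guards: states
the EM never visits get an absorbing self-transition after fitting; mixture
weights are floored at 1e-12 and renormalized; with the variance prior the
EM objective is penalized, so the plain log-likelihood may dip by parts in
1e6 near convergence — the monotonicity test allows that much and no more.

One joint multichannel HMM is used, so the segmentation is shared across
channels; a variant in which epochs are matched but of unequal length per
channel is not attempted (no concrete mechanism for it is defined).

## Bump modeling

The complex Morlet family is parameterized by its cycle count: at analysis
frequency f, σ_t = cycles/(2πf) with cycles = 7, the classic EEG trade-off
between time and frequency resolution. Wavelets are L1-normalized so
|W(f,t)| estimates the instantaneous amplitude of a tone at f; the grid is
1–30 Hz in 0.5 Hz steps, and samples within one wavelet support (4σ_t) of
either end are flagged per frequency and excluded from statistics and peak
search.

Per-frequency z-scoring uses the mean and SD of |W| over the valid columns
of that recording only (per-recording, not pooled across subjects —
pooling would leak between-subject amplitude differences into a
within-recording salience measure). Constant rows are zeroed with a
warning.

Atoms are half-ellipsoids with five parameters (t_c, f_c, w_t, w_f, a).
Extraction is greedy matching pursuit: take the map maximum, seed widths
from the half-maximum extent (an ellipsoid reaches half its height at
0.866 of its width), fit one atom by bounded least squares on a ±3-width
window, subtract, repeat; stop below 2 z-units of fitted amplitude or at 50
atoms. Bounds keep each atom's support inside its fit window so the global
residual energy cannot increase (asserted as an invariant). The
least-squares residual is evaluated on a time-decimated grid (≤ ~64 columns
across the window) — the atom is smooth, and this cuts fitting cost several
fold without measurable bias at the 0.25 s / 1 Hz tolerances the recovery
tests use.

The scalar BM feature aggregates a channel's atom list to the rate of
atoms with f_c inside the band (bumps/s over the valid duration), averaged
over the region's channels. Amplitude-based aggregations
(`mean_amplitude`, `total_amplitude`) are available; the rate was chosen as
the most direct reading of "how often transient synchrony events occur".
Bump extraction is band-agnostic, so one pass per channel serves all three
BM bands (`channel_bump_models` + the `models=` argument).

## Feature bank, selection, classification

The 16 primaries (7 EpEn + 9 BM region/band pairs) are standardized over
subjects and squared, giving 32 candidates; squares add a simple non-linear
term. Standardization statistics always come from the training subjects of
the current fold.

OFR ranks candidates by squared cosine with the residual target (labels
encoded ±1), orthogonalizing the remaining columns and the target against
each pick; ties break by column order, and ranking stops early if the
remainder is numerically rank-deficient. Two identities anchor the tests:
the first pick equals the brute-force max-correlation column, and the final
cumulative explained variance equals the OLS R² on all columns.

The random-probe stopping rule appends 100 probes — seeded row permutations
of randomly chosen real columns, preserving marginals while destroying any
association with the target (i.i.d. Gaussian probes by flag) — ranks real
and probe columns jointly, and keeps a real candidate while the estimated
probe-rank CDF at its rank is below the risk (default 10%). The CDF
estimate uses the permutation-test continuity correction
(B+1)/(n_probes+1), so the risk→0 limit correctly selects nothing. Two
calibration facts are worth stating plainly: for a *single* null candidate
the acceptance probability equals the risk (verified by simulation), but
the *family-wise* false-selection probability over 32 null candidates is
far higher (~0.9 at risk 0.10), because the first candidate is the best of
32 — the rule controls a per-candidate, not a family-wise, error rate.
Users who need family-wise control should lower the risk accordingly.

Pairwise SVMs use a degree-2 polynomial kernel (coef0 = 1, γ = 1/p,
C = 1), with penalty weights inversely proportional to class frequency —
the margin-calibration device for unbalanced cohorts. Platt's sigmoid is
fitted on out-of-fold decision values from a stratified 3-fold internal
split (fitting it on training decisions would be optimistically steep),
with Platt's Bayes-corrected targets and inverse-class-frequency sample
weights; the weighting keeps a majority class from dragging the sigmoid
intercept, which would otherwise bias LOSO below chance under the null
(each held-out subject's class is the training fold's minority).
Pairwise posteriors couple into class posteriors via
Pr(C_i|x) = 1/(Σ_{j≠i} 1/Pr_ij − (K−2)) with Pr_ij clipped to
[1e-6, 1−1e-6] against division blow-ups; the raw coupled values need not
sum to one, so they are explicitly normalized (for K = 2 the formula is
already exact and normalization is a no-op). Argmax ties break by class
order (SCI, AD, MCI, OtherPath).

LOSO evaluation re-runs standardization, per-pair selection and SVM/Platt
fitting inside every training fold (`selection.mode="nested"`, the
default); `"global"` performs one selection on the full data first —
useful to reproduce a single reported feature list, but optimistically
biased — and `"none"` uses all provided columns. Per-fold metadata
(training ids, training means, selected features) is retained so leakage
can be audited mechanically.

## The synthetic cohort generator

The generator reproduces the *statistical skeleton* the analysis assumes,
not real EEG. Each subject is a sum of: 1/f-power background noise
(σ = 10 µV broadband); an occipital-dominant alpha rhythm (individual peak
frequency ~N(10, 0.5) Hz, amplitude 2× background at occipital channels,
gains 0.5 posterior / 0.25 elsewhere); and Gaussian-windowed oscillatory
bursts planted by Poisson processes (≈4 cycles long, peak amplitudes
2.5–4× background, sparse base rates of 0.04/0.10/0.10 bursts/s/channel in
theta/alpha/beta). Burst rates are kept sparse deliberately: transient
events are rare by definition, and the detector's per-recording z-scoring
self-normalizes dense activity, which would wash group differences out of
any count-based feature.

Group effects: AD receives the full effect sizes, MCI half, OtherPath draws
each effect per subject uniformly between zero and full (clinical
heterogeneity), SCI none. The entropy effect makes the alpha rhythm more
deterministic (a variance-preserving mixture from narrowband noise toward a
phase-stable sinusoid, weight 1−exp(−1.5·effect)) *and* weaker
(amplitude × exp(−0.25·effect)) — jointly the "reduced complexity, reduced
alpha power" signature; both movements lower the fitted-density entropy, so
EpEn decreases monotonically in the effect size. The burst effects add
0.16 bursts/s to frontal theta and remove 0.05 bursts/s of beta for
AD-like subjects. Every planted burst is logged (channel, time, frequency,
amplitude), so detection can be scored against ground truth.

Not emulated: artifacts (blinks, EMG, electrode pops), volume
conduction/field spread, non-stationary drowsiness effects, age covariates
(age can be attached as metadata but is never simulated). Consequently,
passing tests demonstrate that the pipeline recovers the intended
structure when it is present and finds nothing when it is absent — they do
not certify performance on clinical recordings, where artifact handling
and inter-subject variability dominate.

EDF I/O is a minimal plain-EDF 16-bit implementation (round trips are
exact to one quantization step; the record duration field limits
non-integral sampling rates to ~6 significant digits); MNE's independent
EDF reader is used as a cross-check in the tests.

## Problem sizes and determinism

Everything is seeded: the generator from `CohortSpec.seed`, HMM and
selection from their config seeds, and the acceptance script derives all
of its seeds from `--seed`. The shipped checks use sizes chosen to make
the statistics decisive while staying desk-scale: 20 subjects per group
for the direction-of-effect sign tests (α = 0.01), 50 seeded maps with up
to 5 planted atoms for bump recovery, 200 seeded runs for the probe null
rates, and 5×40 subjects for the LOSO null calibration. The full clinical
cohort sizes (22/49/58/40) remain the generator defaults.

## Known limitations

- EpEn values grow with channel count D (they are joint differential
  entropies); compare only within a fixed region/band definition.
- The literal entropy estimator is not scale-consistent; it is retained
  for comparison, not recommended.
- The probe rule's risk is per-candidate; family-wise error under many
  null candidates approaches certainty (see above).
- Greedy bump extraction merges overlapping events and under-counts
  bursts once band occupancy is high; density features saturate there.
- LOSO with small groups has high variance; confusion-matrix rows based
  on few subjects move in large quanta.
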