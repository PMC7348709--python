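# Methods

This note documents the models, algorithmic conventions and numerical
choices behind `fibrillens`, and what the synthetic-data experiments do
and do not demonstrate.

## Signal model and preprocessing

Recordings are single-lead ECGs, nominally 300 Hz and 9–60 s, in µV.
Each record is characterised by an amplitude SNR,
`20·log10(max|x| / 4σ(x))` on the raw signal (the 20·log10 amplitude-ratio
convention; the maximum plays the role of signal amplitude, four standard
deviations that of noise amplitude), then band-pass filtered with a
6th-order Butterworth (0.5–45 Hz) applied forward and backward. "6th
order" refers to the one-pass design; the bidirectional pass squares the
magnitude response and zeroes the phase. The filter is realised as
second-order sections for numerical stability.

R peaks are detected on the filtered signal with a Pan–Tompkins-style
chain: 5–25 Hz band-limiting, differentiation, squaring, 150 ms
moving-window integration, and an adaptive signal/noise threshold
recursion with a 200 ms refractory period. Detections are refined to the
local extremum of |signal| within ±40 ms, iterated to a fixed point (so
refinement is idempotent) — working on |signal| makes detection
polarity-invariant. Records in which fewer than three R peaks are found
are rejected (the acceptance gate); all thresholds are configurable.

## Median beat and landmarks

The median beat is the per-sample median of all complete −250…+450 ms
windows around detected R peaks (211 samples at 300 Hz; windows that
would leave the record are dropped). Landmarks:

* `Rp`: argmax of |median beat|;
* `QRSon` / `QRSoff`: the second-to-last derivative sign change before
  `Rp` and the second one after it;
* `Pp` / `Tp`: argmax of the baseline-referenced |median beat| on
  `[0, QRSon)` and `(QRSoff, end]`;
* `Toff`: first sign change after `Tp`.

Conventions that the sign-change definition leaves open were fixed as
follows. The derivative is the first difference of a Savitzky–Golay
smoothed copy (11 samples, order 3); values within 0.2% of the maximum
absolute derivative count as zero, and zero runs are skipped rather than
counted as changes — otherwise flat segments and negligible wiggles
would generate spurious landmarks. Amplitudes are always read off the
raw (unsmoothed) median beat. Searches for `Pp`/`Tp` are bounded by
`QRSon`/`QRSoff` rather than literally by `Rp` so QRS flank samples
cannot win the argmax, and ties resolve toward the sample nearest `Rp`.
One correction proved necessary in practice: a zero-phase 0.5 Hz
high-pass removes the periodic mean of the beat train, so the filtered
median beat rides at an isoelectric level tens of µV below zero; the
`Pp`/`Tp` absolute-maximum searches therefore first re-reference the
beat to its baseline sample (80 ms before `Rp`). Without this the
isoelectric plateau outweighs any genuine P wave.

The 11 morphological features follow directly: five landmark intervals
in ms; amplitudes at `Pp`, `QRSon`, `QRSoff`, `Tp` relative to the
baseline sample 80 ms before `Rp` (a 3-sample mean is available by
config); `AQRS` as the max−min excursion over `[QRSon, QRSoff]`
(baseline-free); and `AQRS/AP`. When |AP| < 1e−6 µV the ratio is capped
at ±10⁴ so downstream standardisation stays finite — the ratio is
heavy-tailed regardless, and a cap preserves orderings without
introducing infinities.

## F-wave features

The dominant waveform is estimated by the segmented beat modulation
principle. Cycles span `[R_i − 100 ms, R_{i+1} − 100 ms)`; the first
140 ms of each cycle (the QRS segment, bracketing normal QRS duration)
is kept at fixed duration, the remaining TUP segment is linearly
resampled to the median-RR TUP length, the beat template is the
per-sample median over normalised cycles, and the dominant signal is
rebuilt by inverse-stretching the template TUP to each cycle's own
length. Head and tail samples outside any full cycle copy the input and
so contribute zero residual. Both segment parameters are config keys.

The residual (record − dominant) is linearly detrended (suppressing
stitching steps at cycle boundaries) and its PSD estimated four ways:
Hamming-tapered periodogram; Welch (1024-sample segments, 50% overlap,
Hamming); Yule–Walker autoregressive of order 16 (coefficients via
statsmodels, spectrum evaluated on a 2049-point grid up to Nyquist); and
Thomson multitaper with time–bandwidth 4 and 7 DPSS tapers. The
estimator parameters are conventional defaults, fixed in config and
recorded with every run. FWFR is the trapezoidal spectral area on
4–10 Hz over the total area; the total spans [0, Nyquist] by default,
with the 0.5–45 Hz prefilter band selectable, since either reading of
"total spectral area" is defensible.

## HRV features

From the RR series in ms: MRR (mean), SDRR (sample SD, n−1), RMSRR, and
PRR50. RMSRR is implemented as the RMS of *successive differences*
(RMSSD): an RMS of the intervals themselves would be of the same order
as MRR (~900 ms), incompatible with the tens-of-ms magnitudes such a
statistic takes on real recordings; a literal-RMS mode exists for
completeness. PRR50 counts only increases ("RR exceeding the previous RR
by more than 50 ms") by default, with the conventional
absolute-difference pNN50 as an option.

## The RSL-ANN

All units are sigmoid; parameters initialise i.i.d. uniform on [−1, 1].
Because the raw features span four orders of magnitude (µV amplitudes in
the thousands vs. unit-scale ratios), inputs are z-scored with
training-set statistics before entering the network — without this the
uniform initialisation saturates immediately. The loss is class-weighted
cross-entropy with w_c = N/(2·N_c) (inverse prevalence, weight 1 on a
balanced set); weighted squared error is available. The loss choice
matches the sigmoid output and the classification objective; weights are
computed from training prevalence and applied consistently to the
monitored validation loss.

Training is full-batch scaled conjugate gradient (Møller's algorithm:
finite-difference curvature along the search direction, Levenberg–
Marquardt style scaling adapted from the quadratic-prediction quality).
One epoch = one SCG iteration. Early stopping keeps the parameters of
the best validation epoch and stops after 6 epochs without improvement
(patience; max 1000 epochs — conventional defaults).

Structuring obeys three hard constraints: at most three hidden layers; a
layer never wider than its predecessor; growth by exactly one neuron (in
an existing layer or as a new size-1 layer). A candidate passes the
screen only if one of up to 10 random draws of the *new* neuron's
parameters (shape-preserved parameters are copied from the current
primitive; when a new layer opens, the re-shaped output weights are also
drawn) lowers the validation loss after exactly one SCG epoch; the drawn
initialisation, not the one-epoch state, seeds the full training.
"Performance" in both the screen and the adoption comparison is the
validation loss (smooth; the misclassification rate is logged
alongside). The stop rules: no acceptable candidate; ten consecutive
rounds in which no candidate beats the primitive (the counter resets on
adoption); zero misclassification (threshold 0.5) on training and
validation. A `max_rounds` cap (default 25) additionally bounds the
loop so a pathological search cannot run unbounded; every round,
candidate, screen outcome and decision is recorded in a search log.
The outer restart loop draws distinct child seeds from a master seed,
runs the whole construction per seed, and keeps the smallest validation
loss (ties: fewer parameters, then lower seed). The restart default in
the package API is 5, which saturates performance on the synthetic
conditions; heavier searches just raise `n_restarts`.

## Evaluation

ROC curves enumerate all unique score thresholds; AUC is trapezoidal
(equal to the tie-adjusted Mann–Whitney statistic, which the tests
verify). The 95% CI uses the Hanley–McNeil standard error by default
(cheap, standard; DeLong available) with the method recorded in the
report. Case 1 picks the threshold minimising |Se − Sp| — a discrete ROC
rarely achieves exact equality — with ties resolved toward higher Se,
since the screening use case favours sensitivity; Case 2 maximises Se
subject to Sp ≥ 0.75, returning a flagged point at maximal available Sp
when the floor is infeasible. Group comparisons use the two-sided
Wilcoxon rank-sum test (exact for tie-free samples of ≤10 per group,
tie-corrected normal approximation otherwise) at α = 0.05; summary
percentiles interpolate linearly between order statistics.

## Synthetic data: what it emulates, and what it does not

Each beat is a sum of Gaussian waves. Besides P, Q, R, S and T the
template carries three small ventricular details — a pre-Q shoulder, a
J wave after S, and a U wave after T. These give every derivative
sign-change rule a well-defined physiologic target (the shoulder crest
for `QRSon`, the J crest for `QRSoff`, the T–U valley for `Toff`), and
because they are ventricular they are identical in AF and non-AF
records, which keeps QRS duration class-independent, as it is
clinically. Ground-truth landmark positions are located independently
of the delineator, by dense-grid extremum search on the noiseless
continuous beat model.

RR intervals are gamma distributed, floored at 300 ms: mean 860 ms with
cv 0.03 for sinus rhythm and mean 720 ms with cv 0.20 for AF, producing
SDRR magnitudes of a few tens vs. ~150 ms and the shorter mean cycle
length typical of AF. AF mode removes the P wave and adds a 40 µV
amplitude-modulated sinusoid whose frequency drifts slowly inside
4–10 Hz with a per-record random phase — the drift and asynchrony with
the beat train prevent the beat-median template from absorbing it, so
it survives into the residual as real F waves do. Broadband Gaussian
noise is added at 15 dB (RMS ratio) by default, a moderately noisy
portable-device condition. Dataset generation jitters amplitudes,
widths, wave centres, RR statistics, F-wave frequency/amplitude and SNR
per record to create realistic between-subject spread; all of these are
the package's fixed study conditions, not tuning knobs.

The generator reproduces the statistical structure the pipeline
*consumes* — landmark geometry, band-limited atrial spectra, RR
irregularity — not waveform realism: there is no baseline wander, no
muscle or electrode artefact, no ectopy, no non-AF arrhythmia class,
and the "other rhythm" heterogeneity of real portable-device data is
absent. Consequently the synthetic classes separate essentially
perfectly (test AUC ≈ 1 at the default conditions, against ~0.91 on
real annotated recordings), and passing the recovery tests demonstrates
that the pipeline is implemented correctly and recovers known structure
— not that it attains any particular accuracy on clinical data.

## Problem sizes and degenerate inputs

The acceptance run and the heaviest test use 300 records (150 per
class) of 30 s at 300 Hz with a 5-restart search — the size at which
every distributional check is stable. Records failing the R-peak gate
are rejected as in the protocol; records accepted but failing a later
feature stage (e.g. a monotone median-beat tail with no T-offset sign
change) are excluded from modelling with the failure logged per stage —
a distinct, logged category, since the protocol itself only excludes on
R-peak grounds. Degenerate inputs raise typed errors: constant signals
(undefined SNR), zero spectral area, too-short records for filtering or
PSD estimation, fewer than two RR intervals.
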