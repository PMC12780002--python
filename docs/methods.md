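# Methods

`neurocode` implements the computational pipeline of a microelectrode-array
(MEA) platform for studying electrical crosstalk between neurons and glioma
cells: extracellular recordings are denoised, spike events ("neural codes")
are detected with a spike-robust threshold and classified into a template
library, their spectral and nonlinear features are extracted, a recurrent
sequence model learns and resynthesises the event stream for use as a
stimulation signal, and tumor-population migration along a microfluidic
channel is quantified by the Cell Migration Center (CMC). Because no
recordings are publicly deposited, every quantitative guarantee in this
package is established on synthetic recordings with known ground truth;
this note documents the models, the defaults and why, and what the
synthetic results do and do not show about real data.

## Signal model and synthetic recordings

A recording is a channels × time int16 matrix (30 kHz sampling, 32-electrode
geometry at 200 µm pitch by default; µV = counts × `uv_per_count`). The
simulator (`neurocode.simulate`) composes, per channel:

* **Neuronal spikes** — biphasic templates (dominant lobe plus an
  opposite-sign rebound), durations drawn from a normal with mean 1.2 ms and
  SD 0.3 ms truncated to 0.9–1.5 ms. Spontaneous firing is a homogeneous
  Poisson process with an enforced 2 ms refractory; setting the rate to
  1/6.5 ms⁻¹ yields the characteristic ≈8.5 ms mean peak-to-peak interval.
* **Tumor potentials** — multiphasic templates (≥3 sign-alternating,
  exponentially decaying lobes), durations log-uniform over 1–15.6 ms;
  inter-event intervals follow a gamma renewal process with coefficient of
  variation 0.32.
* **Noise and interference** — Gaussian baseline noise (default SD 2.4 µV,
  i.e. excursions of roughly ±5 µV at second-scale windows), plus optional
  shared 50 Hz line pickup and slow (0.5 Hz) drift as the common-mode
  target.
* **Coupling attenuation** — optionally, template amplitudes are scaled by
  the cell–electrode coupling ratio V_in/V_s of an equivalent-circuit
  divider: the membrane (R_m ∥ C_m) in series feeds a node shunted by the
  seal resistance R_seal in parallel with the measurement path (electrode
  impedance + amplifier input resistance), evaluated at a 1 kHz reference
  frequency (mid-band of spike energy). The ratio rises monotonically with
  R_seal, → ~1 as R_seal → ∞ and → 0 as R_seal → 0.

Every operation is a pure function of (config, seed), and the ground-truth
event table lists each inserted spike, so detection can be scored exactly.
The simulator does *not* model electrode drift, bursting, spike-amplitude
adaptation, correlated (1/f) noise, or overlapping-unit waveform
superposition beyond linear summation — so passing tests demonstrate
algorithmic correctness under the declared statistics, not robustness to
every pathology of real recordings.

## Preprocessing

Common-mode interference is removed by subtracting the per-sample
cross-channel mean (with few channels this leaks a −1/n copy of each spike
into the other channels; at the platform's 8–32 channels the leak is well
below threshold). All Butterworth stages are order-2 and applied
forward–backward (`sosfiltfilt`), so they are zero-phase: spike peak
indices move by at most one sample through the default chains. Two chains
are documented: `detect` (common-mode → 1–3000 Hz bandpass) and `lfp`
(common-mode → 3 kHz low-pass). A Savitzky–Golay smoother (order 5, frame
501) is available; its convolution weights are computed on a normalised
window so that degree-≤5 polynomials are reproduced to ~1e-12 even at the
501-sample frame (the naive unnormalised least-squares weights only reach
~1e-7). Wavelet shrinkage uses db4, 4 levels, the MAD noise estimate on the
finest detail scale and the universal threshold, with soft shrinkage by
default and hard thresholding as an option; an adaptive scalar Kalman
filter (random-walk state, innovation-adapted measurement variance) is
provided as an optional denoiser.

## Spike detection: the modified threshold

For a trace x, the naive threshold is AVG + factor·STD with AVG/STD the
plain mean and *population* (divisor n) standard deviation, factor ∈ [3, 5]
(default 4, the midpoint; values outside warn but are allowed). Spikes
inflate STD, so the estimate is refined: samples with |x| ≥ threshold are
excluded and AVG′/STD′ recomputed over the survivors, giving the modified
threshold AVG′ + factor·STD′. One refinement pass is the default (an
`iterate` flag repeats to a fixed point). The refined SD is a strictly
better noise estimate in mean absolute error whenever spikes are present —
the acceptance script measures a ~35–50% MAE reduction at 5 Hz spikes and
SNR 8 over 100 seeds (the magnitude depends on spike rate and SNR; the
direction is the invariant).

Peak picking returns local extrema of |x| above the modified threshold
separated by a refractory interval (default 2 ms, matching the simulator).
The full pipeline (`detect.run_detection`) estimates the threshold on the
bandpassed trace — where the background is Gaussian and the refinement is
meaningful — but picks peaks on a hard-threshold wavelet-denoised version
of the same channel (denoised *before* the bandpass so the finest-scale
noise estimate is unbiased). Rationale: a plain 4σ extremum rule on 1–3 kHz
bandpassed Gaussian noise fires ~1.2 times per second (Rice-rate physics),
which at sparse firing rates caps precision; hard shrinkage zeroes
sub-threshold noise structure without subtracting amplitude from spikes,
driving the false-positive rate to ~0/s while leaving recall ≈ 1, so F1
reaches ≥0.99 at SNR 5, factor 4. Waveform snippets (default 2 ms pre/post)
are extracted peak-aligned; windows that spill past the trace edge are
dropped with a warning, and snippets whose extremum moved off-centre
(collisions) are re-centred once or dropped.

## Neural-code classification

The code library grows sequentially: the first waveform founds code C001
and *remains its template* (no averaging); each later waveform is compared
digit-by-digit against existing templates in library order. A sample
position is consistent when |w_j − t_j| / max(|t_peak|, ε) ≤ tolerance
(default 30%); deviations are measured relative to the template's peak
amplitude, not the per-sample value, because per-sample ratios blow up at
zero crossings. A waveform joins the first template whose consistent
fraction reaches the consistency minimum (default 90%); otherwise it founds
a new code (a `best_match` option assigns to the maximum-consistency
template instead). Envelope min/max per sample track the member range for
plotting. The procedure is order-dependent by construction (documented);
the discovered code count is non-increasing in tolerance and non-decreasing
in the consistency minimum. Profiles (normalised code frequencies, top-k
selection with ties broken by code id) are compared by per-code deltas and
a chi-square test on the 2 × k count table.

The classification is alignment-sensitive: a one-sample misalignment on a
steep flank can fail the 30% band. Real spike waveforms at 30 kHz have a
dominant extremum, which keeps the peak-alignment stable under noise; the
test fixtures therefore use spike-like shapes (dominant first lobe) rather
than arbitrary oscillatory shapes.

## Feature extraction

Time-domain properties use documented conventions: duration is the span
where |x| ≥ 10% of peak; rise time 10→90% on the leading edge; decay
90→10% on the trailing edge (crossings linearly interpolated); slope is
the 10–90% amplitude change over the rise time; "interval integral" is the
area under |x| between the duration crossings; "frequency" is the dominant
rFFT component of the snippet (the event-rate reading of frequency is a
recording-level quantity, not a per-waveform one). All time properties are
amplitude-scale invariant.

Band power integrates a Welch PSD over named bands (theta 4–8 Hz, gamma
30–100 Hz) and reports the fraction relative to a declared total band
(default 1–150 Hz); Morlet energies are mean squared CWT magnitudes over 8
logarithmic bands spanning 0.1–5 kHz (3 log-spaced centre frequencies per
band). Hilbert–Huang features come from an in-package empirical mode
decomposition (cubic-spline envelopes through extrema with mirrored
boundary extrema; sifting stops on the Cauchy criterion SD < 0.2 or after
50 passes, flagged by a warning): per IMF we report energy, the
amplitude²-weighted mean Hilbert instantaneous frequency (5% edge trim),
and sample entropy (m = 2, r = 0.2·SD, computed on ≤600 points).
Reconstruction Σ IMFs + residual = x is exact by construction. Feature
selection is recursive feature elimination over a shrinkage-regularised
linear discriminant (deterministic; importance = |coefficient|), and the
discrimination surface is evaluated by seeded stratified k-fold
cross-validation with a pluggable shallow classifier (LDA by default) — a
deliberate stand-in surface for deep classifiers, evaluated on the same
feature families.

## Sequence model and statistically controlled generation

Events are (code type, inter-peak interval) pairs. The model embeds the
code type (16-d by default), appends the interval (normalised by the
training mean) and runs two recurrent layers (LSTM default, GRU
selectable; 128 hidden units, dropout 0.3 between layers) into two heads:
softmax code-type logits trained with cross-entropy, and a scalar interval
regressor with ReLU activation (bias initialised at the normalised mean so
the head does not start dead) trained with MSE; the combined loss is a 1:1
weighted sum. Training is Adam (lr 0.001 default) over truncated-BPTT
windows (32 events, stride 31, left-padded), with a held-out 10% window
split, early stopping at patience 5, and global-norm gradient clipping at
5. The whole engine is NumPy with analytic backpropagation — gradients are
verified against central finite differences for both cell types in the
test suite — and all randomness flows through seeded generators, so
training and generation are bit-reproducible on a fixed thread setup.

Generation starts from a seed slice of the corpus and proceeds
autoregressively. The statistical control mechanism has two arms:

* **type control** — predicted probabilities are multiplied by
  (target_freq / running_generated_freq)^β (β = 1 default) and
  renormalised, which provably pulls empirical frequencies toward the
  target (the training distribution unless overridden);
* **timing control** — the interval prediction is perturbed by a residual
  drawn from the *empirical* pool of training residuals (sorted, ≤5000
  values), so the marginal interval distribution matches the training
  marginal rather than a Gaussian approximation; every interval is floored
  at one sample period, so positivity is absolute.

Generation stops once every common code type (top-k of the training
frequencies, k = 70 by default) has at least `min_common_occurrences`
(default 70) occurrences, or at a hard length cap (flagged, not an error).
Fidelity is validated by chi-square on the code-count tables and a
two-sample Kolmogorov–Smirnov test on intervals. At the scaled-down
condition used in acceptance (2000 events over a 10-code alphabet, 10
epochs, 64 hidden units, lr 0.005, batch 8 — the paper-scale lr is tuned
for a far larger corpus), chi-square passes at α = 0.01 in 20/20 seeds and
the K-S calibration on same-distribution control samples passes in ≥90%
of runs.

`render_stimulus` concatenates library templates at the generated
intervals on a zero baseline (intervals shorter than a template span
overlap-add with a warning); `recover_sequence` inverts it by detecting
peaks (threshold at half the smallest template peak) and classifying each
against the fixed library by best-match consistency. At zero noise the
round trip recovers the exact (code, interval) sequence up to sample-grid
quantisation; the trailing interval is unobservable by construction.

## Migration: the Cell Migration Center

With 1-based electrode index i, pitch d and per-electrode counts CN_i,

    CMC = Σ_i (i · CN_i · d) / Σ_i CN_i ,

so d ≤ CMC ≤ n·d whenever any cell is present; a zero-count day is
*undefined* and reported as missing, never 0. CMC is exactly
translation-covariant (one-electrode shift adds d) and invariant to count
scaling. The synthetic migration generator advances a persistent cell
population: each cell keeps a fixed standard-normal offset z, and its day-t
position is µ(t) + 2.5·z electrodes with µ(t) = 1 + (plateau − 1)(1 −
e^(−t/τ)), binned to the nearest electrode (half-pitch binning). Because
each cell's binned position is monotone in the front position, the CMC
trajectory is non-decreasing and, at a matched seed, the hyper-invasive
profile (τ = 1.3 d, plateau electrode 28) dominates the normal profile
(τ = 6 d, plateau 12) on every day — reaching ≥90% of its plateau CMC by
day 4. An independent per-day multinomial draw would reproduce the same
marginal heatmaps but cannot guarantee those shape properties at finite
cell number, which is why the persistent-population model was chosen.
Condition comparison runs per-day paired t-tests across replicate series
(with a K-S normality check on the paired differences logged); identical
replicates report t = 0, p = 1.

## Problem sizes and determinism

Default test and acceptance runs use: 60 s × 8 channels at 30 kHz for the
detection F1 condition; 30 s × 4 channels of pure noise for the
false-positive rate; 10 planted templates × 50 instances for codebook
recovery; 1000 random tables for the CMC property sweep; 2000-event
corpora for the sequence model; 100 random sequences for the render round
trip; 7-day, 32-electrode, 1000-cell tables for migration. These sizes
make the full suite run in well under a minute apiece while leaving the
statistical margins wide (e.g. the binomial SD of a 0.25 frequency at
n = 10⁴ is 0.004 against a 0.02 band). All stochastic stages take explicit
seeds; the CLI derives per-stage seeds from the global seed via
`numpy.random.SeedSequence`.

## Known limitations

* The codebook is order-dependent and over-splits at low SNR (noise can
  push a waveform below 90% consistency with its true template), which is
  why recovery is scored by adjusted Rand index rather than exact label
  agreement.
* The sequence model's interval head predicts a conditional mean; without
  the empirical-residual timing control its marginal interval distribution
  would be too narrow to pass a K-S test against training data.
* `compare_conditions` with the paper-scale n = 3 replicates has very low
  power; the per-day p-values are reported for completeness, and ordering
  claims in the tests rest on the means.
* The Kalman and Savitzky–Golay stages are provided but not part of the
  default detection chain; at frame 501 (16.7 ms) the smoother is an
  LFP-scale tool and would destroy millisecond spikes.
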