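"""Feature extraction for neuron-vs-tumor signal discrimination.

Four feature families:

* time-domain waveform properties (dominant frequency, duration, rise and
  decay times, amplitude, slope, interval integral) measured at documented
  10%/90%-of-peak thresholds;
* band power over named LFP bands (theta 4–8 Hz, gamma 30–100 Hz) from a
  Welch spectral estimate;
* Morlet continuous-wavelet band energies across 0.1–5 kHz;
* Hilbert–Huang features: empirical mode decomposition by cubic-spline
  sifting, then per-IMF energy, amplitude-weighted mean instantaneous
  frequency, and sample entropy.

Feature selection uses recursive feature elimination over a regularised
linear discriminant; the discrimination surface is evaluated by seeded
k-fold cross-validation with a pluggable shallow classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal
from scipy.interpolate import CubicSpline
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.feature_selection import RFE
from sklearn.metrics import classification_report
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from neurocode.errors import ConfigError, ValidationError
from neurocode.detect import Waveform

BAND_PRESETS = {"theta": (4.0, 8.0), "gamma": (30.0, 100.0)}


# ---------------------------------------------------------------------------
# Time-domain waveform properties
# ---------------------------------------------------------------------------


@dataclass
class WaveformProperties:
    frequency_hz: float
    duration_ms: float
    rise_time_ms: float
    decay_time_ms: float
    amplitude_uv: float
    slope_uv_per_ms: float
    interval_integral: float
    flagged: bool = False


def _cross_time(mag: np.ndarray, idx0: int, idx1: int, level: float) -> float:
    """Linear-interpolated crossing position between adjacent samples."""
    a, b = mag[idx0], mag[idx1]
    if b == a:
        return float(idx1)
    return idx0 + (level - a) / (b - a) * (idx1 - idx0)


def _leading_cross(mag: np.ndarray, peak: int, level: float) -> float:
    """Last upward crossing of `level` before the peak (sample units)."""
    for i in range(peak, 0, -1):
        if mag[i - 1] < level <= mag[i]:
            return _cross_time(mag, i - 1, i, level)
    return 0.0


def _trailing_cross(mag: np.ndarray, peak: int, level: float) -> float:
    """First downward crossing of `level` after the peak (sample units)."""
    for i in range(peak, mag.size - 1):
        if mag[i] >= level > mag[i + 1]:
            return _cross_time(mag, i, i + 1, level)
    return float(mag.size - 1)


def waveform_properties(
    waveform: Waveform | np.ndarray, rate_hz: float
) -> WaveformProperties:
    """Measure a peak-aligned waveform.

    Conventions (documented, amplitude-scale invariant): duration is the
    span where |x| >= 10% of the peak; rise time is the 10%->90% interval on
    the leading edge; decay time 90%->10% on the trailing edge; slope is
    the 10-90% amplitude change over the rise time; the interval integral
    is the area under |x| between the duration crossings; frequency is the
    dominant spectral component of the snippet.
    """
    if isinstance(waveform, Waveform):
        x = waveform.samples_uv
        peak = waveform.alignment_index
    else:
        x = np.asarray(waveform, dtype=float)
        peak = int(np.argmax(np.abs(x)))
    mag = np.abs(x)
    peak_amp = mag[peak]
    if peak_amp == 0:
        warnings.warn("flat waveform: properties undefined")
        nan = float("nan")
        return WaveformProperties(nan, nan, nan, nan, 0.0, nan, nan, flagged=True)

    ms_per_sample = 1e3 / rate_hz
    lo10 = _leading_cross(mag, peak, 0.1 * peak_amp)
    lo90 = _leading_cross(mag, peak, 0.9 * peak_amp)
    hi90 = _trailing_cross(mag, peak, 0.9 * peak_amp)
    hi10 = _trailing_cross(mag, peak, 0.1 * peak_amp)
    duration_ms = (hi10 - lo10) * ms_per_sample
    rise_ms = (lo90 - lo10) * ms_per_sample
    decay_ms = (hi10 - hi90) * ms_per_sample

    spec = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate_hz)
    dom = float(freqs[1:][np.argmax(spec[1:])]) if x.size > 2 else float("nan")

    i0, i1 = int(np.floor(lo10)), int(np.ceil(hi10))
    integral = float(np.trapezoid(mag[i0 : i1 + 1], dx=1.0 / rate_hz))
    slope = 0.8 * peak_amp / rise_ms if rise_ms > 0 else float("inf")
    return WaveformProperties(
        frequency_hz=dom,
        duration_ms=float(duration_ms),
        rise_time_ms=float(rise_ms),
        decay_time_ms=float(decay_ms),
        amplitude_uv=float(x[peak]),
        slope_uv_per_ms=float(slope),
        interval_integral=integral,
    )


# ---------------------------------------------------------------------------
# Band power
# ---------------------------------------------------------------------------


def band_power(
    trace: np.ndarray,
    rate_hz: float,
    band: str | tuple[float, float],
    total_band: tuple[float, float] = (1.0, 150.0),
    nperseg: int | None = None,
) -> tuple[float, float]:
    """(fraction, absolute) power in a band from a Welch estimate.

    ``band`` may be a preset name ("theta", "gamma") or (low, high) in Hz.
    The fraction is relative to the declared ``total_band``; fractions over
    disjoint sub-bands of it sum to <= 1.
    """
    if isinstance(band, str):
        if band not in BAND_PRESETS:
            raise ConfigError(f"unknown band preset {band!r}")
        band = BAND_PRESETS[band]
    lo, hi = band
    nyq = rate_hz / 2.0
    if not (0 < lo < hi):
        raise ConfigError(f"invalid band ({lo}, {hi})")
    if hi > nyq:
        raise ConfigError(f"band upper edge {hi} Hz above Nyquist {nyq:g} Hz")
    x = np.asarray(trace, dtype=float)
    if x.size < 2 * rate_hz / lo:
        raise ValidationError(
            "trace shorter than 2 periods of the band's low edge"
        )
    if nperseg is None:
        nperseg = int(min(x.size, round(4 * rate_hz / lo)))
    freqs, psd = signal.welch(x, fs=rate_hz, nperseg=nperseg)

    def _integrate(f_lo: float, f_hi: float) -> float:
        m = (freqs >= f_lo) & (freqs <= f_hi)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[m], freqs[m]))

    absolute = _integrate(lo, hi)
    t_lo, t_hi = total_band
    total = _integrate(t_lo, min(t_hi, nyq))
    fraction = absolute / total if total > 0 else 0.0
    return fraction, absolute


# ---------------------------------------------------------------------------
# Morlet wavelet band energies
# ---------------------------------------------------------------------------


def morlet_energies(
    trace: np.ndarray,
    rate_hz: float,
    band_edges: np.ndarray | None = None,
    scales_per_band: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean squared CWT magnitude per band (Morlet mother wavelet).

    Default edges: 8 logarithmic bands across 0.1–5 kHz. Returns
    (energy vector, band edges). Energies are non-negative and scale
    quadratically with amplitude.
    """
    if band_edges is None:
        band_edges = np.logspace(np.log10(100.0), np.log10(5000.0), 9)
    band_edges = np.asarray(band_edges, dtype=float)
    nyq = rate_hz / 2.0
    if band_edges.min() <= 0 or band_edges.max() >= nyq:
        raise ConfigError("band edges must lie inside (0, Nyquist)")
    if np.any(np.diff(band_edges) <= 0):
        raise ConfigError("band edges must be strictly increasing")
    x = np.asarray(trace, dtype=float)
    wavelet = "morl"
    fc = pywt.central_frequency(wavelet)
    energies = np.empty(band_edges.size - 1)
    all_freqs, owners = [], []
    for b in range(band_edges.size - 1):
        fs_band = np.logspace(
            np.log10(band_edges[b]), np.log10(band_edges[b + 1]), scales_per_band + 2
        )[1:-1]
        all_freqs.extend(fs_band)
        owners.extend([b] * fs_band.size)
    scales = fc * rate_hz / np.asarray(all_freqs)
    coef, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / rate_hz)
    power = np.abs(coef) ** 2
    owners = np.asarray(owners)
    for b in range(band_edges.size - 1):
        energies[b] = power[owners == b].mean() if (owners == b).any() else 0.0
    return energies, band_edges


# ---------------------------------------------------------------------------
# Hilbert-Huang transform (EMD by cubic-spline sifting)
# ---------------------------------------------------------------------------


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    maxima = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
    minima = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0)) + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, boundary extrema mirrored."""
    n = x.size
    t = np.concatenate([[-idx[0]], idx, [2 * (n - 1) - idx[-1]]])
    v = np.concatenate([[x[idx[0]]], x[idx], [x[idx[-1]]]])
    t, uniq = np.unique(t, return_index=True)
    return CubicSpline(t, v[uniq])(np.arange(n))


def emd(
    x: np.ndarray,
    max_imfs: int = 8,
    sd_stop: float = 0.2,
    max_sift: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical mode decomposition by standard sifting.

    Each sifting pass subtracts the mean of the cubic-spline upper and
    lower envelopes; a pass stops on the Cauchy criterion
    ``sum((h_prev - h)^2)/sum(h_prev^2) < sd_stop`` or after ``max_sift``
    iterations (flagged via a warning). Decomposition stops when the
    residual has fewer than 4 extrema or ``max_imfs`` is reached. The
    residual is defined as ``x - sum(imfs)``, so reconstruction is exact.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ConfigError("trace too short for EMD (need >= 64 samples)")
    residual = x.copy()
    imfs = []
    for _ in range(max_imfs):
        maxima, minima = _extrema(residual)
        if maxima.size + minima.size < 4 or maxima.size < 2 or minima.size < 2:
            break
        h = residual.copy()
        converged = False
        for _ in range(max_sift):
            maxima, minima = _extrema(h)
            if maxima.size < 2 or minima.size < 2:
                break
            mean_env = 0.5 * (_envelope(h, maxima) + _envelope(h, minima))
            h_new = h - mean_env
            denom = float(np.sum(h * h))
            if denom == 0 or float(np.sum(mean_env * mean_env)) / denom < sd_stop**2:
                h = h_new
                converged = True
                break
            h = h_new
        if not converged:
            warnings.warn("sifting iteration cap reached; IMF accepted as-is")
        imfs.append(h)
        residual = residual - h
    imfs = np.asarray(imfs) if imfs else np.empty((0, x.size))
    return imfs, x - imfs.sum(axis=0)


def mean_instantaneous_frequency(imf: np.ndarray, rate_hz: float) -> float:
    """Amplitude²-weighted mean Hilbert instantaneous frequency (Hz)."""
    analytic = signal.hilbert(imf)
    phase = np.unwrap(np.angle(analytic))
    inst = np.diff(phase) * rate_hz / (2.0 * np.pi)
    amp2 = np.abs(analytic[:-1]) ** 2
    trim = max(int(0.05 * inst.size), 1)
    inst, amp2 = inst[trim:-trim], amp2[trim:-trim]
    keep = inst > 0
    if not keep.any() or amp2[keep].sum() == 0:
        return 0.0
    return float(np.average(inst[keep], weights=amp2[keep]))


def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """SampEn(m, r = r_frac * SD); computed on at most 600 points."""
    x = np.asarray(x, dtype=float)
    if x.size > 600:
        step = int(np.ceil(x.size / 600))
        x = x[::step]
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_frac * sd

    def _count(mm: int) -> int:
        n = x.size - mm + 1
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
        return int((d[np.triu_indices(n, k=1)] <= r).sum())

    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        return float("inf")
    return float(-np.log(a / b))


def hht_features(
    trace: np.ndarray, rate_hz: float, max_imfs: int = 6
) -> dict:
    """Per-IMF nonlinear features: energy, mean instantaneous frequency,
    sample entropy; plus the IMFs and residual for inspection."""
    imfs, residual = emd(np.asarray(trace, dtype=float), max_imfs=max_imfs)
    features = {}
    for k, imf in enumerate(imfs, start=1):
        features[f"imf{k}_energy"] = float(np.sum(imf * imf))
        features[f"imf{k}_mif_hz"] = mean_instantaneous_frequency(imf, rate_hz)
        features[f"imf{k}_sampen"] = sample_entropy(imf)
    return {"features": features, "imfs": imfs, "residual": residual}


# ---------------------------------------------------------------------------
# Feature selection and shallow classification
# ---------------------------------------------------------------------------


def _default_estimator():
    # regularised linear discriminant: deterministic, importance = |coef|
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")


def rfe_select(
    feature_matrix: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str] | None = None,
    k: int = 12,
    estimator=None,
) -> list[str]:
    """Recursive feature elimination down to k features.

    Iteratively refits the base scorer and drops the lowest-importance
    feature until k remain. Deterministic (the base LDA has no randomness).
    """
    X = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValidationError("need >= 2 classes for feature selection")
    if X.shape[0] <= k:
        raise ValidationError("need more samples than selected features")
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ConfigError("feature_names length != number of columns")
    if k >= X.shape[1]:
        if k > X.shape[1]:
            warnings.warn(
                f"k={k} >= {X.shape[1]} features; returning all features"
            )
        return list(names)
    rfe = RFE(estimator or _default_estimator(), n_features_to_select=k, step=1)
    rfe.fit(X, y)
    return [n for n, keep in zip(names, rfe.support_) if keep]


def classify_signals(
    feature_matrix: np.ndarray,
    labels: np.ndarray,
    folds: int = 5,
    estimator=None,
    seed: int = 0,
) -> dict:
    """Seeded stratified k-fold cross-validation with a shallow classifier.

    Returns overall accuracy plus a per-class precision/recall report.
    """
    X = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("need >= 2 classes")
    if folds > counts.min():
        raise ValidationError(
            f"folds={folds} exceeds smallest class count {counts.min()}"
        )
    if counts.max() / counts.min() > 4:
        warnings.warn("classes are heavily imbalanced; accuracy may mislead")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(estimator or _default_estimator(), X, y, cv=cv)
    report = classification_report(y, pred, output_dict=True, zero_division=0)
    return {
        "accuracy": float((pred == y).mean()),
        "report": report,
        "predictions": pred,
    }


def feature_vector(
    waveform: Waveform, rate_hz: float, include_hht: bool = False
) -> dict[str, float]:
    """Fixed-order named features for one waveform (provenance excluded)."""
    props = waveform_properties(waveform, rate_hz)
    out = {
        "frequency_hz": props.frequency_hz,
        "duration_ms": props.duration_ms,
        "rise_time_ms": props.rise_time_ms,
        "decay_time_ms": props.decay_time_ms,
        "amplitude_uv": props.amplitude_uv,
        "slope_uv_per_ms": props.slope_uv_per_ms,
        "interval_integral": props.interval_integral,
    }
    energies, edges = morlet_energies(waveform.samples_uv, rate_hz)
    for b, e in enumerate(energies):
        out[f"morlet_{edges[b]:.0f}_{edges[b + 1]:.0f}hz"] = float(e)
    if include_hht and waveform.samples_uv.size >= 64:
        out.update(hht_features(waveform.samples_uv, rate_hz)["features"])
    return out
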