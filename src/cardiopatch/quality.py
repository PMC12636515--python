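"""Signal-quality metrics: template SNR, baseline-drift amplitude,
instantaneous-frequency maps, and lag-searched cross-correlation.

SNR here is *template SNR*: beats are aligned on their R peaks, the ensemble
average is taken as the signal estimate, and each beat's departure from the
template as noise, giving 10 log10(sum(template^2) * n_beats / sum(residual^2)).
This makes the number comparable across runs of this package without a
noise-free reference.

Drift amplitude is the peak-to-peak excursion of the sub-0.5 Hz baseline,
expressed relative to the peak-to-peak of the remaining (cardiac) signal —
a dimensionless, scale-invariant convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass
class QualityMetrics:
    snr_db: float
    drift_amplitude: float
    xcorr_max: float = float("nan")


@dataclass
class TimeFrequencyMap:
    times: np.ndarray        # s
    frequencies: np.ndarray  # Hz
    magnitude: np.ndarray    # |S(f, t)|, shape (n_freq, n_time)
    ridge: np.ndarray        # spectral-centroid instantaneous frequency (Hz)


def snr(x: np.ndarray, fs: float, rpeaks) -> float:
    """Template SNR in dB from R-peak-aligned ensemble averaging.

    The per-beat window is the median RR, split 40%/60% before/after the R
    peak so windows tile the record; beats whose window leaves the record are
    skipped.
    """
    x = np.asarray(x, dtype=float)
    idx = np.asarray(rpeaks.indices if hasattr(rpeaks, "indices") else rpeaks)
    if idx.size < 5:
        raise ValueError("need at least 5 detected beats for template SNR")
    rr = int(round(float(np.median(np.diff(idx)))))
    before, after = int(round(0.4 * rr)), int(round(0.6 * rr))
    beats = [x[i - before:i + after] for i in idx
             if i - before >= 0 and i + after <= x.size]
    if len(beats) < 5:
        raise ValueError("need at least 5 fully-contained beats")
    stack = np.stack(beats)
    template = stack.mean(axis=0)
    residual = stack - template
    p_sig = float(np.sum(template ** 2)) * stack.shape[0]
    p_noise = float(np.sum(residual ** 2))
    if p_noise == 0:
        return float("inf")
    return 10.0 * np.log10(p_sig / p_noise)


def drift_amplitude(x: np.ndarray, fs: float) -> float:
    """Peak-to-peak of the sub-0.5 Hz baseline relative to the cardiac p2p."""
    x = np.asarray(x, dtype=float)
    if x.size < 10 * fs:
        raise ValueError("need at least 10 s of signal")
    if np.ptp(x) == 0:
        return 0.0
    sos = sps.butter(4, 0.5, btype="lowpass", fs=fs, output="sos")
    baseline = sps.sosfiltfilt(sos, x)
    cardiac = x - baseline
    if np.ptp(cardiac) == 0:
        return 0.0
    # discard the zero-phase filter's warm-up at both ends (2 cutoff periods)
    trim = min(int(4 * fs), x.size // 4)
    core = baseline[trim:x.size - trim]
    return float(np.ptp(core) / np.ptp(cardiac))


def instantaneous_frequency(x: np.ndarray, fs: float,
                            window_s: float = 1.0,
                            overlap: float = 0.75) -> TimeFrequencyMap:
    """Short-time spectrum with a first-moment (spectral centroid) ridge,

    IF(t) = sum_f f |S(f,t)|^2 / sum_f |S(f,t)|^2.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 256:
        raise ValueError("need at least 256 samples")
    nper = int(round(window_s * fs))
    nover = int(round(overlap * nper))
    f, t, S = sps.stft(x, fs=fs, nperseg=nper, noverlap=nover,
                       padded=False, boundary=None)
    mag = np.abs(S)
    power = mag ** 2
    denom = power.sum(axis=0)
    denom[denom == 0] = np.finfo(float).tiny
    ridge = (f[:, None] * power).sum(axis=0) / denom
    return TimeFrequencyMap(times=t, frequencies=f, magnitude=mag, ridge=ridge)


def xcorr_coefficient(a: np.ndarray, b: np.ndarray, fs: float = 250.0,
                      max_lag_s: float = 0.5):
    """Lag-searched Pearson correlation.

    Scans lags |L| <= max_lag_s, picks the lag maximizing |rho|, and returns
    (rho_at_that_lag, lag_samples) — so an inverted copy reports -1.0 at its
    aligning lag rather than being hidden by the absolute value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    max_lag = int(round(max_lag_s * fs))
    max_lag = min(max_lag, a.size - 2)
    best_rho, best_lag = 0.0, 0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            xa, xb = a[lag:], b[:b.size - lag]
        else:
            xa, xb = a[:a.size + lag], b[-lag:]
        if xa.size < 2 or np.ptp(xa) == 0 or np.ptp(xb) == 0:
            continue
        rho = float(np.corrcoef(xa, xb)[0, 1])
        if abs(rho) > abs(best_rho):
            best_rho, best_lag = rho, lag
    return best_rho, best_lag


def quality_metrics(x: np.ndarray, fs: float, rpeaks,
                    reference: np.ndarray = None) -> QualityMetrics:
    xc = float("nan")
    if reference is not None:
        xc, _ = xcorr_coefficient(x, reference, fs=fs)
    return QualityMetrics(snr_db=snr(x, fs, rpeaks),
                          drift_amplitude=drift_amplitude(x, fs),
                          xcorr_max=xc)
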