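"""Pan-Tompkins QRS detection and heart-rate / HRV reporting.

The detector is the classic adaptive-threshold formulation: 5-15 Hz bandpass,
five-point derivative, squaring, 150 ms moving-window integration, dual
signal/noise peak tracking with threshold = NPK + 0.25 (SPK - NPK) and update
coefficients 0.125 / 0.25, a 200 ms refractory period, and search-back at
1.66x the running mean RR using half the threshold. Accepted peaks are
refined to the raw-signal local maximum within +/-50 ms.

Heart rate is reported per update window (default 6 s) as 60 / mean(RR) over
the RR intervals whose midpoint falls inside the window; windows with fewer
than two peaks are flagged missing. HRV follows the standard time-domain
definitions: SDNN (population SD of RR, ms), RMSSD (RMS of successive RR
differences, ms) and pNN50 (% successive differences > 50 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class PanTompkinsConfig:
    band: tuple = (5.0, 15.0)       # Hz
    integration_window_s: float = 0.150
    refractory_s: float = 0.200
    signal_update: float = 0.125    # running-estimate coefficients
    noise_update: float = 0.25
    searchback_factor: float = 1.66
    refine_radius_s: float = 0.050


@dataclass
class RPeakSet:
    indices: np.ndarray
    fs: float
    thresholds: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def rr_seconds(self) -> np.ndarray:
        return np.diff(self.indices) / self.fs


@dataclass
class VitalsReport:
    heart_rate_bpm: np.ndarray      # per window, NaN where missing
    window_starts_s: np.ndarray
    window_s: float
    sdnn_ms: float
    rmssd_ms: float
    pnn50_pct: float
    hr_min_bpm: float
    hr_max_bpm: float


def _moving_window_integration(x: np.ndarray, n: int) -> np.ndarray:
    return np.convolve(x, np.ones(n) / n, mode="same")


def pan_tompkins(x: np.ndarray, fs: float,
                 config: PanTompkinsConfig = PanTompkinsConfig()) -> RPeakSet:
    """Detect R peaks; returns indices into the raw signal."""
    x = np.asarray(x, dtype=float)
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    if not np.any(x != x[0] if x.size else False):
        return RPeakSet(indices=np.empty(0, dtype=int), fs=fs)

    sos = sps.butter(2, config.band, btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    # five-point derivative: (1/8)(2x[n] + x[n-1] - x[n-3] - 2x[n-4]) * fs
    kernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) * fs / 8.0
    deriv = np.convolve(bp, kernel, mode="same")
    squared = deriv ** 2
    mwi = _moving_window_integration(squared, int(round(config.integration_window_s * fs)))

    refractory = int(round(config.refractory_s * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return RPeakSet(indices=np.empty(0, dtype=int), fs=fs)

    # threshold initialization on the first 2 s
    head = mwi[:int(2 * fs)]
    spk = 0.6 * head.max()
    npk = 0.5 * head.mean()

    accepted: list = []
    thresholds = []
    rr_history: list = []

    def refine(idx: int) -> int:
        r = int(round(config.refine_radius_s * fs))
        lo, hi = max(0, idx - r), min(x.size, idx + r + 1)
        return lo + int(np.argmax(x[lo:hi]))

    i = 0
    while i < cand.size:
        idx = cand[i]
        thr = npk + 0.25 * (spk - npk)
        thresholds.append(thr)
        peak = mwi[idx]
        if peak > thr:
            if accepted and idx - accepted[-1] < refractory:
                i += 1
                continue
            if accepted:
                rr_history.append(idx - accepted[-1])
                rr_history[:] = rr_history[-8:]
            accepted.append(idx)
            spk = config.signal_update * peak + (1 - config.signal_update) * spk
        else:
            npk = config.noise_update * peak + (1 - config.noise_update) * npk
            # search-back: if the expected beat is overdue, take the best
            # missed candidate above half threshold
            if accepted and rr_history:
                mean_rr = float(np.mean(rr_history))
                if idx - accepted[-1] > config.searchback_factor * mean_rr:
                    window = cand[(cand > accepted[-1] + refractory) & (cand < idx)]
                    if window.size:
                        best = window[np.argmax(mwi[window])]
                        if mwi[best] > 0.5 * thr:
                            rr_history.append(best - accepted[-1])
                            rr_history[:] = rr_history[-8:]
                            accepted.append(best)
                            spk = 0.25 * mwi[best] + 0.75 * spk
        i += 1

    refined = sorted({refine(idx) for idx in accepted})
    # refinement may merge neighbours; enforce the refractory invariant
    final = []
    for idx in refined:
        if not final or idx - final[-1] >= refractory:
            final.append(idx)
    return RPeakSet(indices=np.asarray(final, dtype=int), fs=fs,
                    thresholds=np.asarray(thresholds))


def heart_rate(rpeaks: RPeakSet, window_s: float = 6.0,
               total_s: float = None):
    """Per-window HR series (bpm); NaN marks windows with < 2 peaks.

    An RR interval contributes to the window containing its midpoint.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    idx = rpeaks.indices
    if total_s is None:
        total_s = (idx[-1] + 1) / rpeaks.fs if idx.size else 0.0
    n_windows = max(1, int(np.floor(total_s / window_s)))
    starts = np.arange(n_windows) * window_s
    hr = np.full(n_windows, np.nan)
    if idx.size >= 2:
        rr = np.diff(idx) / rpeaks.fs
        mid = (idx[:-1] + idx[1:]) / 2.0 / rpeaks.fs
        which = np.floor(mid / window_s).astype(int)
        for w in range(n_windows):
            rr_w = rr[which == w]
            if rr_w.size >= 1 and np.sum((idx / rpeaks.fs >= starts[w])
                                         & (idx / rpeaks.fs < starts[w] + window_s)) >= 2:
                hr[w] = 60.0 / rr_w.mean()
    return hr, starts


def hrv_metrics(rpeaks: RPeakSet, window_s: float = 6.0,
                total_s: float = None) -> VitalsReport:
    """Time-domain HRV over all detected RR intervals plus the windowed HR
    series with its min/max."""
    if rpeaks.indices.size < 3:
        raise ValueError("need at least 3 R peaks for HRV")
    rr_ms = rpeaks.rr_seconds * 1000.0
    diffs = np.diff(rr_ms)
    sdnn = float(np.std(rr_ms))          # population convention
    rmssd = float(np.sqrt(np.mean(diffs ** 2))) if diffs.size else 0.0
    pnn50 = float(100.0 * np.mean(np.abs(diffs) > 50.0)) if diffs.size else 0.0
    hr, starts = heart_rate(rpeaks, window_s, total_s)
    valid = hr[~np.isnan(hr)]
    return VitalsReport(
        heart_rate_bpm=hr, window_starts_s=starts, window_s=window_s,
        sdnn_ms=sdnn, rmssd_ms=rmssd, pnn50_pct=pnn50,
        hr_min_bpm=float(valid.min()) if valid.size else float("nan"),
        hr_max_bpm=float(valid.max()) if valid.size else float("nan"))


def match_peaks(detected: np.ndarray, truth: np.ndarray, fs: float,
                tolerance_s: float = 0.050):
    """Greedy one-to-one matching of detected vs ground-truth peaks.

    Returns (sensitivity, ppv, n_matched).
    """
    tol = tolerance_s * fs
    truth = np.asarray(truth)
    used = np.zeros(truth.size, dtype=bool)
    matched = 0
    for d in np.asarray(detected):
        j = np.argmin(np.abs(truth - d)) if truth.size else -1
        if j >= 0 and not used[j] and abs(truth[j] - d) <= tol:
            used[j] = True
            matched += 1
    sens = matched / truth.size if truth.size else float("nan")
    ppv = matched / len(detected) if len(detected) else float("nan")
    return sens, ppv, matched
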