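"""Preprocessing chain: mains notch, diagnostic bandpass, baseline correction,
segmentation, per-window normalization.

Fixed pipeline order: notch -> bandpass -> baseline-correct -> segment ->
normalize. All filtering is zero-phase (forward-backward), so R-peak
locations move by at most one sample. Baseline estimation uses a two-stage
median filter (200 ms then 600 ms) subtracted from the signal, which removes
sub-0.5 Hz wander while preserving ST-segment levels — important because the
MI class is defined by its ST displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class FilterSpec:
    notch_freq: float = 50.0   # Hz
    notch_q: float = 30.0
    band_low: float = 0.5      # Hz
    band_high: float = 40.0    # Hz
    filter_order: int = 4

    def __post_init__(self):
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if self.notch_q <= 0:
            raise ValueError("notch_q must be positive")


@dataclass
class SegmentSet:
    windows: list                # equal-length float arrays
    window_s: float
    stride_s: float
    offsets: np.ndarray          # start sample of each window
    fs: float = 250.0


def notch_filter(x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase IIR notch at ``spec.notch_freq`` (>= 30 dB rejection)."""
    if fs <= 2 * spec.notch_freq:
        raise ValueError("fs must exceed twice the notch frequency")
    b, a = sps.iirnotch(spec.notch_freq, spec.notch_q, fs=fs)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float))


def bandpass_filter(x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase Butterworth bandpass over the diagnostic band."""
    if spec.band_high >= fs / 2:
        raise ValueError("band_high must be below Nyquist")
    sos = sps.butter(spec.filter_order, [spec.band_low, spec.band_high],
                     btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def baseline_correct(x: np.ndarray, fs: float) -> np.ndarray:
    """Remove baseline wander by median-filter baseline subtraction.

    A 200 ms median removes QRS complexes, a subsequent 600 ms median removes
    P/T waves; what remains tracks only the sub-0.5 Hz baseline, which is
    subtracted.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    k1 = int(round(0.2 * fs)) | 1   # odd kernel lengths
    k2 = int(round(0.6 * fs)) | 1
    baseline = sps.medfilt(sps.medfilt(x, k1), k2)
    return x - baseline


def segment(x: np.ndarray, fs: float, window_s: float,
            stride_s: float) -> SegmentSet:
    """Cut into equal windows; the trailing partial window is dropped."""
    if stride_s <= 0:
        raise ValueError("stride must be positive")
    x = np.asarray(x, dtype=float)
    w = int(round(window_s * fs))
    s = int(round(stride_s * fs))
    if x.size < w:
        raise ValueError("signal shorter than one window")
    offsets = np.arange(0, x.size - w + 1, s)
    return SegmentSet(windows=[x[o:o + w].copy() for o in offsets],
                      window_s=window_s, stride_s=stride_s,
                      offsets=offsets, fs=fs)


def normalize(window: np.ndarray):
    """Per-window z-score. Constant windows map to zeros with a flag.

    Returns (normalized, degenerate_flag).
    """
    window = np.asarray(window, dtype=float)
    sd = window.std()
    if sd == 0:
        return np.zeros_like(window), True
    return (window - window.mean()) / sd, False


def preprocess_signal(x: np.ndarray, fs: float,
                      spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Full filtering chain (notch -> bandpass -> baseline-correct)."""
    return baseline_correct(bandpass_filter(notch_filter(x, fs, spec), fs, spec), fs)
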