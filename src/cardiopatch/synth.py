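"""Synthetic single-lead ECG with controllable pathology, wear orientation and noise.

Each beat is a sum of Gaussian wave components on a beat phase
:math:`\\varphi \\in (-\\pi, \\pi]`,

.. math:: s(\\varphi) = \\sum_{w \\in \\{P,Q,R,S,T\\}}
          a_w \\exp\\!\\left(-\\frac{(\\varphi-\\theta_w)^2}{2 b_w^2}\\right),

with the R peak anchored at phase zero, so every record carries *analytic*
ground truth: exact R-peak sample indices and per-beat fiducial spans (P wave,
QRS complex, ST segment, T wave). RR intervals are drawn from a Gaussian
instantaneous-heart-rate model with optional respiratory modulation.

Pathology is expressed through the waveform features a cardiologist reads:

* **MI** (myocardial infarction) — an additive ST-segment shift;
* **AR** (arrhythmia) — inflated RR variability plus premature (ectopic)
  beats with a compensatory pause;
* **AH** (atrial hypertrophy) — enlarged/widened P wave;
* **NR** (normal rhythm) — identity.

Wear-position misplacement of the 120°-symmetric triangular patch is modelled
as an invertible affine-plus-morphology transform per orientation
(baseline shift, amplitude scaling, polarity, and a spectral-smoothing shape
warp), and noise as baseline wander + mains hum + broadband Gaussian +
Poisson-timed motion bursts.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

WAVE_NAMES = ("P", "Q", "R", "S", "T")
CLASS_LABELS = ("NR", "AR", "AH", "MI")
ORIENTATION_LABELS = ("O0", "O120", "O240")

#: Half-width of a Gaussian wave, in standard deviations, used to convert a
#: (theta, b) pair into an onset/offset fiducial span.
FIDUCIAL_HALF_WIDTH_SD = 2.5


@dataclass(frozen=True)
class WaveParams:
    """Angular position (rad), amplitude (mV) and width (rad) per wave.

    Ordering ``theta_P < theta_Q < theta_R < theta_S < theta_T`` is required,
    with the R peak at phase 0 by convention.
    """

    theta: dict = field(default_factory=lambda: {
        "P": -np.pi / 3, "Q": -np.pi / 12, "R": 0.0,
        "S": np.pi / 12, "T": np.pi / 2,
    })
    amp: dict = field(default_factory=lambda: {
        "P": 0.15, "Q": -0.10, "R": 1.00, "S": -0.15, "T": 0.30,
    })
    width: dict = field(default_factory=lambda: {
        "P": 0.20, "Q": 0.05, "R": 0.05, "S": 0.05, "T": 0.30,
    })

    def __post_init__(self):
        thetas = [self.theta[w] for w in WAVE_NAMES]
        if not all(a < b for a, b in zip(thetas, thetas[1:])):
            raise ValueError("wave angles must satisfy theta_P < ... < theta_T")
        if any(self.width[w] <= 0 for w in WAVE_NAMES):
            raise ValueError("wave widths must be positive")
        if self.amp["R"] <= 0:
            raise ValueError("R amplitude must be positive")


@dataclass(frozen=True)
class RhythmModel:
    """Gaussian instantaneous-HR model with respiratory sinus modulation."""

    mean_hr: float = 70.0          # bpm
    hr_sd: float = 3.0             # bpm
    respiratory_mod_freq: float = 0.25   # Hz
    respiratory_mod_depth: float = 0.05  # fraction of HR

    def __post_init__(self):
        if not 20.0 <= self.mean_hr <= 240.0:
            raise ValueError("mean_hr must lie in [20, 240] bpm")
        if self.hr_sd < 0:
            raise ValueError("hr_sd must be non-negative")
        if not 0.0 <= self.respiratory_mod_depth < 1.0:
            raise ValueError("respiratory_mod_depth must lie in [0, 1)")


@dataclass(frozen=True)
class PathologyProfile:
    """Per-class waveform modifiers; only the active label's fields may differ
    from identity."""

    label: str = "NR"
    st_shift: float = 0.0              # mV, MI only
    rr_irregularity_factor: float = 1.0  # multiplies hr_sd, AR only
    ectopic_prob: float = 0.0          # per-beat premature-beat probability, AR only
    p_amp_scale: float = 1.0           # AH only
    p_width_scale: float = 1.0         # AH only

    def __post_init__(self):
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")
        active = {
            "NR": (),
            "MI": ("st_shift",),
            "AR": ("rr_irregularity_factor", "ectopic_prob"),
            "AH": ("p_amp_scale", "p_width_scale"),
        }[self.label]
        identity = {"st_shift": 0.0, "rr_irregularity_factor": 1.0,
                    "ectopic_prob": 0.0, "p_amp_scale": 1.0, "p_width_scale": 1.0}
        for name, ident in identity.items():
            if name not in active and getattr(self, name) != ident:
                raise ValueError(
                    f"{name} must stay at identity for label {self.label}")
        if self.label == "AR" and self.rr_irregularity_factor < 1.0:
            raise ValueError("rr_irregularity_factor must be >= 1")
        if not 0.0 <= self.ectopic_prob <= 1.0:
            raise ValueError("ectopic_prob must be a probability")


#: Default per-class profiles: clear but non-trivial separability at 30 s.
DEFAULT_PROFILES = {
    "NR": PathologyProfile("NR"),
    "MI": PathologyProfile("MI", st_shift=0.2),
    "AR": PathologyProfile("AR", rr_irregularity_factor=4.0, ectopic_prob=0.1),
    "AH": PathologyProfile("AH", p_amp_scale=2.0, p_width_scale=1.5),
}


@dataclass(frozen=True)
class PositionModel:
    """One of the three stable placements of the triangular patch.

    ``O0`` is the standard placement (identity). Misplaced orientations scale,
    flip, offset and morphologically smooth the trace — the distortion modes a
    rotated single-lead patch produces (baseline shift, amplitude change,
    waveform shape alteration). Each transform is linear-plus-offset and
    exactly invertible.
    """

    orientation: str = "O0"
    amplitude_scale: float = 1.0
    polarity: int = 1
    baseline_offset: float = 0.0  # mV
    morphology_mix: float = 0.0   # in [0, 1]

    def __post_init__(self):
        if self.orientation not in ORIENTATION_LABELS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")
        if not 0.0 <= self.morphology_mix <= 1.0:
            raise ValueError("morphology_mix must lie in [0, 1]")
        if self.orientation == "O0" and (
                self.amplitude_scale != 1.0 or self.polarity != 1
                or self.baseline_offset != 0.0 or self.morphology_mix != 0.0):
            raise ValueError("O0 must be the identity transform")

    @classmethod
    def for_orientation(cls, orientation: str) -> "PositionModel":
        return DEFAULT_POSITIONS[orientation]


DEFAULT_POSITIONS = {
    "O0": PositionModel("O0"),
    "O120": PositionModel("O120", amplitude_scale=0.6, polarity=-1,
                          baseline_offset=0.1, morphology_mix=0.3),
    "O240": PositionModel("O240", amplitude_scale=0.7, polarity=1,
                          baseline_offset=-0.1, morphology_mix=0.5),
}

#: Time constant (s) of the Gaussian spectral-smoothing shape warp.
WARP_SIGMA_S = 0.012


@dataclass(frozen=True)
class NoiseModel:
    """Additive contamination: respiration-band wander, mains hum, broadband
    Gaussian noise, and Poisson-timed motion-artifact bursts."""

    wander_freq: float = 0.3      # Hz
    wander_amp: float = 0.1      # mV
    powerline_freq: float = 50.0  # Hz (device mains filter target)
    powerline_amp: float = 0.02  # mV
    broadband_sd: float = 0.02   # mV
    burst_rate: float = 2.0      # events/min
    burst_amp: float = 0.3       # mV

    def __post_init__(self):
        for name in ("wander_amp", "powerline_amp", "broadband_sd",
                     "burst_amp", "burst_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


NO_NOISE = NoiseModel(wander_amp=0.0, powerline_amp=0.0, broadband_sd=0.0,
                      burst_rate=0.0, burst_amp=0.0)


@dataclass
class SyntheticRecord:
    """A labelled synthetic record plus its full ground truth.

    ``samples`` is the observed trace; ``clean_samples`` the noise-free signal
    at the same orientation. ``fiducials`` holds, per fully-contained beat, the
    half-open sample spans ``[onset, offset)`` of the P wave, the QRS complex,
    the ST segment and the T wave. Generation parameters are retained so that
    downstream operators can resynthesize (e.g. to inflate RR variability)
    while keeping fiducials analytic.
    """

    samples: np.ndarray
    fs: float
    clean_samples: np.ndarray
    rpeak_indices: np.ndarray
    fiducials: list          # per beat: {"P": (on, off), "QRS": ..., "ST": ..., "T": ...}
    class_label: str = "NR"
    orientation_label: str = "O0"
    seed: int = 0
    wave: WaveParams = field(default_factory=WaveParams)
    rhythm: RhythmModel = field(default_factory=RhythmModel)
    duration: float = 10.0
    rr_seconds: np.ndarray = field(default_factory=lambda: np.empty(0))
    hr_draws: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "SyntheticRecord":
        return copy.deepcopy(self)

    def validate(self) -> None:
        if np.any(np.diff(self.rpeak_indices) <= 0):
            raise ValueError("rpeak_indices must be strictly increasing")
        if self.clean_samples.size != self.samples.size:
            raise ValueError("clean_samples must match samples in length")
        for beat in self.fiducials:
            for on, off in beat.values():
                if not (0 <= on <= off <= self.n_samples):
                    raise ValueError("fiducial span out of bounds")


# ---------------------------------------------------------------------------
# rhythm + waveform synthesis


def _draw_rr(rhythm: RhythmModel, duration: float, rng: np.random.Generator):
    """Draw beat-to-beat RR intervals (s) covering [0, duration] with margin.

    Returns (rr, hr_draws): each RR comes from an instantaneous-HR draw
    ``N(mean_hr, hr_sd)`` modulated by the respiratory sinusoid at the beat's
    provisional time.
    """
    rr, hr_draws = [], []
    t = 0.0
    # one extra beat on each side so edge beats have both neighbours
    while t < duration + 2.5 * 60.0 / rhythm.mean_hr:
        hr = rhythm.mean_hr + rhythm.hr_sd * rng.standard_normal()
        hr = float(np.clip(hr, 20.0, 240.0))
        mod = 1.0 + rhythm.respiratory_mod_depth * np.sin(
            2 * np.pi * rhythm.respiratory_mod_freq * t)
        hr_draws.append(hr)
        interval = 60.0 / (hr * mod)
        rr.append(interval)
        t += interval
    return np.asarray(rr), np.asarray(hr_draws)


def _apply_ectopics(rr: np.ndarray, prob: float, rng: np.random.Generator):
    """Premature beats: shorten RR_i to 60%, lengthen RR_{i+1} by the deficit
    (compensatory pause). Beat count and total time are preserved."""
    rr = rr.copy()
    for i in range(len(rr) - 1):
        if rng.random() < prob:
            deficit = 0.4 * rr[i]
            rr[i] -= deficit
            rr[i + 1] += deficit
    return rr


def _synthesize(wave: WaveParams, rr: np.ndarray, fs: float, duration: float):
    """Render the Gaussian-sum waveform from an RR sequence.

    Beat centres sit at ``rr[0]/2 + cumsum(rr[1:])`` shifted so the first
    centre is half an interval in; phase is piecewise linear between beat
    midpoints, 2π per beat, R at phase 0.
    """
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    centers = np.concatenate([[rr[0] / 2.0], rr[0] / 2.0 + np.cumsum(rr[1:])])
    # nearest beat for every sample via midpoints
    midpoints = (centers[:-1] + centers[1:]) / 2.0
    k = np.searchsorted(midpoints, t)
    ck = centers[k]
    rr_prev = np.empty_like(centers)
    rr_next = np.empty_like(centers)
    rr_prev[0], rr_prev[1:] = rr[0], np.diff(centers)
    rr_next[:-1], rr_next[-1] = np.diff(centers), rr[-1]
    local_rr = np.where(t < ck, rr_prev[k], rr_next[k])
    phase = 2 * np.pi * (t - ck) / local_rr

    samples = np.zeros(n)
    for w in WAVE_NAMES:
        samples += wave.amp[w] * np.exp(
            -((phase - wave.theta[w]) ** 2) / (2 * wave.width[w] ** 2))

    # ground truth: R peaks and fiducials for beats fully inside the record
    rpeaks, fiducials = [], []
    half = FIDUCIAL_HALF_WIDTH_SD
    for i, c in enumerate(centers):
        idx = int(np.floor(c * fs + 0.5))
        if not 0 <= idx < n:
            continue
        prev_rr = rr_prev[i]
        next_rr = rr_next[i]

        def to_time(theta):
            scale = (prev_rr if theta < 0 else next_rr) / (2 * np.pi)
            return c + theta * scale

        spans = {}
        th, am, bw = wave.theta, wave.amp, wave.width
        p_on, p_off = to_time(th["P"] - half * bw["P"]), to_time(th["P"] + half * bw["P"])
        q_on = to_time(th["Q"] - half * bw["Q"])
        s_off = to_time(th["S"] + half * bw["S"])
        t_on, t_off = to_time(th["T"] - half * bw["T"]), to_time(th["T"] + half * bw["T"])
        for name, (a, b) in {"P": (p_on, p_off), "QRS": (q_on, s_off),
                             "ST": (s_off, t_on), "T": (t_on, t_off)}.items():
            spans[name] = (int(np.floor(a * fs + 0.5)), int(np.floor(b * fs + 0.5)))
        if any(on < 0 or off > n for on, off in spans.values()):
            continue
        rpeaks.append(idx)
        fiducials.append(spans)

    return samples, np.asarray(rpeaks, dtype=int), fiducials


def generate_record(wave: WaveParams = None, rhythm: RhythmModel = None,
                    fs: float = 250.0, duration: float = 10.0,
                    seed: int = 0) -> SyntheticRecord:
    """Generate a clean normal-rhythm record with exact ground truth.

    Parameters
    ----------
    wave, rhythm
        Waveform and rhythm parameters; defaults give a textbook normal beat
        at 70 bpm with mild HR variability.
    fs
        Sampling rate (Hz), >= 100.
    duration
        Record length in seconds; must fit at least two beats at ``mean_hr``.
    seed
        Seeds the RR draw; generation is fully deterministic given it.
    """
    wave = wave or WaveParams()
    rhythm = rhythm or RhythmModel()
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if duration * rhythm.mean_hr / 60.0 < 2:
        raise ValueError("duration must cover at least 2 beats")
    rng = np.random.default_rng(seed)
    rr, hr_draws = _draw_rr(rhythm, duration, rng)
    samples, rpeaks, fiducials = _synthesize(wave, rr, fs, duration)
    rec = SyntheticRecord(
        samples=samples, fs=fs, clean_samples=samples.copy(),
        rpeak_indices=rpeaks, fiducials=fiducials, class_label="NR",
        orientation_label="O0", seed=seed, wave=wave, rhythm=rhythm,
        duration=duration, rr_seconds=rr, hr_draws=hr_draws)
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# pathology


def apply_pathology(record: SyntheticRecord, profile: PathologyProfile,
                    seed: int = 0) -> SyntheticRecord:
    """Imprint a disease class onto a clean record.

    MI adds ``st_shift`` mV over every ST span (flat within the span, short
    cosine ramps just outside it, so the mean ST displacement is exact).
    AR resynthesizes the waveform with ``hr_sd`` multiplied by
    ``rr_irregularity_factor`` and premature beats inserted with
    ``ectopic_prob``. AH resynthesizes with the P amplitude and width scaled.
    Must be applied before position/noise (samples still equal clean).
    """
    if not np.array_equal(record.samples, record.clean_samples):
        raise ValueError("apply_pathology expects a noise-free record")
    if record.orientation_label != "O0":
        raise ValueError("apply_pathology expects standard orientation")

    if profile.label == "NR":
        out = record.copy()
        out.class_label = "NR"
        return out

    if profile.label == "MI":
        out = record.copy()
        ramp_n = max(1, int(round(0.016 * record.fs)))
        delta = np.zeros(out.n_samples)
        for beat in out.fiducials:
            on, off = beat["ST"]
            delta[on:off] = profile.st_shift
            up = np.arange(1, ramp_n + 1) / (ramp_n + 1)
            lo = max(0, on - ramp_n)
            delta[lo:on] = profile.st_shift * up[ramp_n - (on - lo):]
            hi = min(out.n_samples, off + ramp_n)
            delta[off:hi] = profile.st_shift * up[::-1][:hi - off]
        out.samples = out.samples + delta
        out.clean_samples = out.samples.copy()
        out.class_label = "MI"
        return out

    rng = np.random.default_rng(np.random.SeedSequence([record.seed, seed, 0xC0DE]))
    if profile.label == "AR":
        rhythm = replace(record.rhythm,
                         hr_sd=record.rhythm.hr_sd * profile.rr_irregularity_factor)
        rr, hr_draws = _draw_rr(rhythm, record.duration, rng)
        rr = _apply_ectopics(rr, profile.ectopic_prob, rng)
        samples, rpeaks, fiducials = _synthesize(record.wave, rr,
                                                 record.fs, record.duration)
        out = record.copy()
        out.samples = samples
        out.clean_samples = samples.copy()
        out.rpeak_indices = rpeaks
        out.fiducials = fiducials
        out.rr_seconds, out.hr_draws = rr, hr_draws
        out.rhythm = rhythm
        out.class_label = "AR"
        out.validate()
        return out

    # AH: same beat times, enlarged P wave
    wave = WaveParams(
        theta=dict(record.wave.theta),
        amp={**record.wave.amp, "P": record.wave.amp["P"] * profile.p_amp_scale},
        width={**record.wave.width,
               "P": record.wave.width["P"] * profile.p_width_scale})
    samples, rpeaks, fiducials = _synthesize(wave, record.rr_seconds,
                                             record.fs, record.duration)
    out = record.copy()
    out.samples = samples
    out.clean_samples = samples.copy()
    out.rpeak_indices = rpeaks
    out.fiducials = fiducials
    out.wave = wave
    out.class_label = "AH"
    out.validate()
    return out


# ---------------------------------------------------------------------------
# wear position


def _warp_gain(n: int, fs: float) -> np.ndarray:
    """Frequency response of the shape warp (real Gaussian low-pass)."""
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    return np.exp(-0.5 * (2 * np.pi * f * WARP_SIGMA_S) ** 2)


def _position_transform(x: np.ndarray, fs: float, pos: PositionModel,
                        inverse: bool = False) -> np.ndarray:
    """y = polarity*scale*[(1-mix) x + mix * smooth(x)] + offset, via rFFT.

    The combined linear gain (1-mix) + mix*G(f) is strictly positive for
    mix < 1, so the transform is exactly invertible.
    """
    gain = (1.0 - pos.morphology_mix) + pos.morphology_mix * _warp_gain(len(x), fs)
    gain = pos.polarity * pos.amplitude_scale * gain
    if inverse:
        return np.fft.irfft(np.fft.rfft(x - pos.baseline_offset) / gain, n=len(x))
    return np.fft.irfft(np.fft.rfft(x) * gain, n=len(x)) + pos.baseline_offset


def apply_position(record: SyntheticRecord, pos: PositionModel) -> SyntheticRecord:
    """Apply a wear-orientation transform; labels compose on the 3-cycle
    O0 → O120 → O240 → O0. R-peak ground truth is preserved as time indices."""
    out = record.copy()
    out.samples = _position_transform(record.samples, record.fs, pos)
    out.clean_samples = _position_transform(record.clean_samples, record.fs, pos)
    old = ORIENTATION_LABELS.index(record.orientation_label)
    step = ORIENTATION_LABELS.index(pos.orientation)
    out.orientation_label = ORIENTATION_LABELS[(old + step) % 3]
    return out


def invert_position(record: SyntheticRecord, pos: PositionModel) -> SyntheticRecord:
    """Exact inverse of :func:`apply_position` for the same transform."""
    out = record.copy()
    out.samples = _position_transform(record.samples, record.fs, pos, inverse=True)
    out.clean_samples = _position_transform(record.clean_samples, record.fs, pos,
                                            inverse=True)
    old = ORIENTATION_LABELS.index(record.orientation_label)
    step = ORIENTATION_LABELS.index(pos.orientation)
    out.orientation_label = ORIENTATION_LABELS[(old - step) % 3]
    return out


# ---------------------------------------------------------------------------
# noise


def add_noise(record: SyntheticRecord, noise: NoiseModel,
              seed: int = 0) -> SyntheticRecord:
    """Contaminate a record; ``clean_samples`` is retained unchanged."""
    rng = np.random.default_rng(np.random.SeedSequence([record.seed, seed, 0xA02E]))
    n = record.n_samples
    t = np.arange(n) / record.fs
    out = record.copy()
    x = record.clean_samples.copy()
    if noise.wander_amp > 0:
        x += noise.wander_amp * np.sin(
            2 * np.pi * noise.wander_freq * t + rng.uniform(0, 2 * np.pi))
    if noise.powerline_amp > 0:
        x += noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq * t + rng.uniform(0, 2 * np.pi))
    if noise.broadband_sd > 0:
        x += noise.broadband_sd * rng.standard_normal(n)
    if noise.burst_rate > 0 and noise.burst_amp > 0:
        n_bursts = rng.poisson(noise.burst_rate * record.duration_s / 60.0)
        width = 0.075  # s, Gaussian envelope SD of a motion artifact
        for _ in range(n_bursts):
            c = rng.uniform(0, record.duration_s)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            x += sign * noise.burst_amp * np.exp(-0.5 * ((t - c) / width) ** 2)
    out.samples = x
    return out


def broadband_sd_for_snr(record: SyntheticRecord, snr_db: float) -> float:
    """White-noise SD giving a known power-ratio SNR against ``clean_samples``."""
    p_sig = float(np.mean(record.clean_samples ** 2))
    return float(np.sqrt(p_sig / 10.0 ** (snr_db / 10.0)))


# ---------------------------------------------------------------------------
# datasets


@dataclass
class Dataset:
    records: list
    class_labels: np.ndarray        # str array, len n
    orientation_labels: np.ndarray  # str array, len n
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int = 0


def _exact_counts(n: int, mix, names) -> list:
    """Largest-remainder apportionment of n into len(mix) integer counts."""
    mix = np.asarray(mix, dtype=float)
    if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("mix proportions must be non-negative and sum to 1")
    raw = mix * n
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    for i in range(n - counts.sum()):
        counts[order[i]] += 1
    return list(counts)


def make_dataset(n: int, class_mix=(0.25, 0.25, 0.25, 0.25),
                 position_mix=(1.0, 0.0, 0.0), fs: float = 250.0,
                 duration: float = 10.0, noise: NoiseModel = None,
                 seed: int = 0, profiles: dict = None,
                 train_frac: float = 0.8) -> Dataset:
    """Generate a labelled dataset with a stratified train/test split.

    ``class_mix`` orders classes as ``(NR, AR, AH, MI)`` and ``position_mix``
    as ``(O0, O120, O240)``; counts are exact up to largest-remainder
    rounding. Per-record seeds derive deterministically from ``seed``, so the
    same call reproduces the dataset byte-for-byte. The split is stratified by
    class, ``train_frac`` going to training within each class.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    noise = NO_NOISE if noise is None else noise
    profiles = profiles or DEFAULT_PROFILES
    class_counts = _exact_counts(n, class_mix, CLASS_LABELS)
    rng = np.random.default_rng(seed)

    records, cls_lab, ori_lab = [], [], []
    for label, count in zip(CLASS_LABELS, class_counts):
        if count == 0:
            continue
        ori_counts = _exact_counts(count, position_mix, ORIENTATION_LABELS)
        orientations = sum(([o] * c for o, c in
                            zip(ORIENTATION_LABELS, ori_counts)), [])
        for orientation in orientations:
            rec_seed = int(rng.integers(0, 2 ** 31 - 1))
            rec = generate_record(fs=fs, duration=duration, seed=rec_seed)
            rec = apply_pathology(rec, profiles[label], seed=rec_seed)
            if orientation != "O0":
                rec = apply_position(rec, PositionModel.for_orientation(orientation))
            rec = add_noise(rec, noise, seed=rec_seed)
            records.append(rec)
            cls_lab.append(label)
            ori_lab.append(orientation)

    cls_lab = np.asarray(cls_lab)
    ori_lab = np.asarray(ori_lab)
    train_idx, test_idx = [], []
    for label in CLASS_LABELS:
        idx = np.flatnonzero(cls_lab == label)
        if idx.size == 0:
            continue
        idx = rng.permutation(idx)
        if idx.size < 2:
            raise ValueError("n too small for a stratified split")
        cut = int(np.clip(round(train_frac * idx.size), 1, idx.size - 1))
        train_idx.extend(idx[:cut])
        test_idx.extend(idx[cut:])
    return Dataset(records=records, class_labels=cls_lab,
                   orientation_labels=ori_lab,
                   train_idx=np.sort(np.asarray(train_idx)),
                   test_idx=np.sort(np.asarray(test_idx)), seed=seed)
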