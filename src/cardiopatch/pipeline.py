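"""End-to-end orchestration: the four app-section analogues — real-time ECG
(streaming vitals), heart-rate data, wearing-position correction, and health
assessment — composed into one reproducible report.

``run_report`` executes preprocess -> vitals -> quality -> position -> IAT.
The position check runs first in the report logic: when the discriminator
places the record outside tolerance, the diagnosis is still emitted but
flagged ``position_compromised``. Reports carry a provenance block (record
generation spec + model seeds) from which every numeric field can be
recomputed exactly.

The consultation section is a pluggable advice interface with an offline
template backend; no network calls are made anywhere in the package.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import iat as iat_mod
from . import position as pos_mod
from . import preprocess, quality, synth, vitals

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class RecordSpec:
    """Everything needed to re-materialize a synthetic record exactly."""

    seed: int = 0
    fs: float = 250.0
    duration: float = 10.0
    class_label: str = "NR"
    orientation: str = "O0"
    noise: synth.NoiseModel = field(default_factory=synth.NoiseModel)
    pathology_seed: int = 0
    noise_seed: int = 0

    def materialize(self) -> synth.SyntheticRecord:
        rec = synth.generate_record(fs=self.fs, duration=self.duration,
                                    seed=self.seed)
        rec = synth.apply_pathology(rec, synth.DEFAULT_PROFILES[self.class_label],
                                    seed=self.pathology_seed)
        if self.orientation != "O0":
            rec = synth.apply_position(
                rec, synth.PositionModel.for_orientation(self.orientation))
        return synth.add_noise(rec, self.noise, seed=self.noise_seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RecordSpec":
        d = dict(d)
        d["noise"] = synth.NoiseModel(**d["noise"])
        return cls(**d)


class TemplateAdvisor:
    """Offline advice backend: maps the diagnosis and vitals to template
    text. Stands where the app's LLM consultation would plug in."""

    TEMPLATES = {
        "NR": "Rhythm and waveform appear within normal limits. Maintain "
              "regular monitoring.",
        "AR": "Irregular R-R intervals detected, consistent with an "
              "arrhythmia pattern. Consider a clinical ECG review.",
        "AH": "P-wave morphology changes suggest atrial hypertrophy. "
              "Follow-up with a physician is advisable.",
        "MI": "ST-segment displacement detected, a myocardial-infarction "
              "pattern. Seek medical attention promptly.",
    }

    def advise(self, label: str, report: "HealthReport") -> str:
        text = self.TEMPLATES[label]
        if report.position is not None and not report.position["within_tolerance"]:
            text += (" Note: the patch appears misplaced; re-position it and "
                     "repeat the measurement before acting on this result.")
        return text


def _top_spans(sal: np.ndarray, slice_len: int, k: int = 3) -> list:
    """Top-k contiguous slice spans by saliency mass."""
    n_slices = len(sal) // slice_len
    mass = sal[:n_slices * slice_len].reshape(n_slices, slice_len).sum(axis=1)
    order = np.argsort(-mass)[:k]
    return [{"start": int(i * slice_len), "end": int((i + 1) * slice_len),
             "mass": float(mass[i])} for i in order]


@dataclass
class HealthReport:
    record_id: str
    schema_version: str
    vitals: dict
    diagnosis: dict
    saliency_top_spans: list
    position: dict
    quality: dict
    advice: str
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def run_report(record_or_spec, iat_weights, position_weights,
               window_s: float = 6.0, advisor=None) -> HealthReport:
    """Full health report for one record.

    ``record_or_spec`` is a SyntheticRecord or a RecordSpec; passing the spec
    puts full generative provenance into the report so it can be reproduced
    field-for-field.
    """
    if iat_weights is None or position_weights is None:
        raise ValueError("model not ready: both trained weights are required")
    spec = None
    if isinstance(record_or_spec, RecordSpec):
        spec = record_or_spec
        record = spec.materialize()
    else:
        record = record_or_spec

    # vitals on the preprocessed signal
    filtered = preprocess.preprocess_signal(record.samples, record.fs)
    rpeaks = vitals.pan_tompkins(filtered, record.fs)
    if rpeaks.indices.size >= 3:
        vr = vitals.hrv_metrics(rpeaks, window_s=window_s,
                                total_s=record.duration_s)
        vitals_block = {
            "heart_rate_bpm": [None if np.isnan(h) else round(float(h), 6)
                               for h in vr.heart_rate_bpm],
            "window_s": vr.window_s, "sdnn_ms": round(vr.sdnn_ms, 6),
            "rmssd_ms": round(vr.rmssd_ms, 6),
            "pnn50_pct": round(vr.pnn50_pct, 6),
            "hr_min_bpm": round(vr.hr_min_bpm, 6),
            "hr_max_bpm": round(vr.hr_max_bpm, 6),
        }
    else:
        vitals_block = {"missing": "fewer than 3 R peaks detected"}

    # quality
    try:
        snr_db = quality.snr(record.samples, record.fs, rpeaks)
    except ValueError:
        snr_db = None
    try:
        drift = quality.drift_amplitude(record.samples, record.fs)
    except ValueError:
        drift = None
    quality_block = {
        "snr_db": None if snr_db is None else round(float(snr_db), 6),
        "drift_amplitude": None if drift is None else round(float(drift), 6),
    }

    # wearing position (checked before the diagnosis is trusted)
    pos_net = pos_mod.net_from_weights(position_weights)
    pos_window = pos_mod.prepare_windows([record],
                                         position_weights.config.input_len)[0]
    assessment = pos_mod.classify_position(pos_net, position_weights, pos_window)
    position_block = assessment.to_dict()

    # diagnosis + saliency
    model = iat_mod.model_from_weights(iat_weights)
    window = iat_mod.prepare_window(record, iat_weights.config.input_len)
    probs = model.predict_proba(window[None, :])[0]
    pred = synth.CLASS_LABELS[int(np.argmax(probs))]
    sal = iat_mod.saliency_for_window(model, window)
    diagnosis_block = {
        "probabilities": {c: round(float(p), 9)
                          for c, p in zip(synth.CLASS_LABELS, probs)},
        "predicted_label": pred,
        "position_compromised": not assessment.within_tolerance,
    }
    spans = _top_spans(sal.per_sample, iat_weights.config.slice_len)

    advisor = advisor or TemplateAdvisor()
    provenance = {
        "schema_version": SCHEMA_VERSION,
        "record_spec": spec.to_dict() if spec is not None else None,
        "iat_seed": int(iat_weights.seed),
        "position_seed": int(position_weights.seed),
        "window_s": window_s,
    }
    report = HealthReport(
        record_id=f"rec-{record.seed}-{record.class_label}-{record.orientation_label}",
        schema_version=SCHEMA_VERSION, vitals=vitals_block,
        diagnosis=diagnosis_block, saliency_top_spans=spans,
        position=position_block, quality=quality_block, advice="",
        provenance=provenance)
    report.advice = advisor.advise(pred, report)
    return report


def reproduce_report(report: HealthReport, iat_weights,
                     position_weights) -> HealthReport:
    """Re-run a report from its provenance block alone."""
    spec_dict = report.provenance.get("record_spec")
    if spec_dict is None:
        raise ValueError("report lacks generative provenance")
    spec = RecordSpec.from_dict(spec_dict)
    return run_report(spec, iat_weights, position_weights,
                      window_s=report.provenance["window_s"])


# ---------------------------------------------------------------------------
# streaming vitals


@dataclass
class StreamUpdate:
    window_index: int
    window_start_s: float
    heart_rate_bpm: float          # NaN when the window is flagged missing
    n_windows_emitted: int


class VitalsStream:
    """Incremental 6-second vitals over a growing sample buffer.

    A window is finalized once the buffer extends one full window past its
    end (update latency of one window), so late-arriving R peaks cannot
    change an emitted value; the emitted HR series equals the batch
    computation on the full record.
    """

    def __init__(self, fs: float, window_s: float = 6.0):
        self.fs = fs
        self.window_s = window_s
        self.buffer = np.empty(0)
        self.emitted = []           # HR per finalized window
        self._next = 0

    def push(self, samples: np.ndarray) -> list:
        """Append samples; returns the StreamUpdates finalized by them."""
        self.buffer = np.concatenate([self.buffer, np.asarray(samples, float)])
        return self._drain(final=False)

    def finish(self) -> list:
        return self._drain(final=True)

    def _drain(self, final: bool) -> list:
        updates = []
        total_s = self.buffer.size / self.fs
        n_complete = int(np.floor(total_s / self.window_s))
        ready = n_complete if final else max(0, n_complete - 1)
        while self._next < ready:
            filtered = preprocess.preprocess_signal(self.buffer, self.fs)
            rpeaks = vitals.pan_tompkins(filtered, self.fs)
            hr, _ = vitals.heart_rate(rpeaks, self.window_s,
                                      total_s=(self._next + 1) * self.window_s)
            value = hr[self._next] if self._next < hr.size else float("nan")
            self.emitted.append(value)
            updates.append(StreamUpdate(
                window_index=self._next,
                window_start_s=self._next * self.window_s,
                heart_rate_bpm=value,
                n_windows_emitted=self._next + 1))
            self._next += 1
        return updates


def stream(record: synth.SyntheticRecord, window_s: float = 6.0,
           chunk_s: float = 1.0) -> list:
    """Feed a record through the streaming path in ``chunk_s`` pieces.

    Returns the list of StreamUpdates; their HR series equals the batch
    per-window series on the same record.
    """
    if record.duration_s < window_s:
        raise ValueError("record shorter than one update window")
    vs = VitalsStream(record.fs, window_s)
    chunk = int(round(chunk_s * record.fs))
    updates = []
    for start in range(0, record.n_samples, chunk):
        updates.extend(vs.push(record.samples[start:start + chunk]))
    updates.extend(vs.finish())
    return updates
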