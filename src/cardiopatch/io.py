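"""Record and weights I/O.

Records travel as a CSV of ``index,mv[,clean_mv]`` plus a JSON sidecar
(``<stem>.json``) holding the sampling rate, labels, R-peak ground truth,
fiducial spans and generation provenance. Model weights are stored as an
``.npz`` of parameter arrays next to a JSON config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import RhythmModel, SyntheticRecord, WaveParams


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def record_to_dict(record: SyntheticRecord) -> dict:
    """JSON-safe dict of everything except the sample arrays."""
    return {
        "fs": record.fs,
        "class_label": record.class_label,
        "orientation_label": record.orientation_label,
        "seed": int(record.seed),
        "duration": record.duration,
        "rpeak_indices": [int(i) for i in record.rpeak_indices],
        "fiducials": [{k: [int(v[0]), int(v[1])] for k, v in beat.items()}
                      for beat in record.fiducials],
        "wave": {"theta": record.wave.theta, "amp": record.wave.amp,
                 "width": record.wave.width},
        "rhythm": dataclasses.asdict(record.rhythm),
    }


def save_record_csv(record: SyntheticRecord, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"index": np.arange(record.n_samples),
                       "mv": record.samples,
                       "clean_mv": record.clean_samples})
    df.to_csv(path, index=False, float_format="%.9g")
    _sidecar(path).write_text(json.dumps(record_to_dict(record), indent=1,
                                         sort_keys=True))
    return path


def load_record_csv(path) -> SyntheticRecord:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    samples = df["mv"].to_numpy(dtype=float)
    clean = (df["clean_mv"].to_numpy(dtype=float)
             if "clean_mv" in df.columns else samples.copy())
    return SyntheticRecord(
        samples=samples, fs=float(meta["fs"]), clean_samples=clean,
        rpeak_indices=np.asarray(meta["rpeak_indices"], dtype=int),
        fiducials=[{k: tuple(v) for k, v in beat.items()}
                   for beat in meta["fiducials"]],
        class_label=meta["class_label"],
        orientation_label=meta["orientation_label"],
        seed=int(meta["seed"]), duration=float(meta["duration"]),
        wave=WaveParams(**meta["wave"]),
        rhythm=RhythmModel(**meta["rhythm"]))


def record_fingerprint(record: SyntheticRecord) -> bytes:
    """Canonical bytes for bitwise-determinism checks."""
    meta = json.dumps(record_to_dict(record), sort_keys=True).encode()
    return meta + record.samples.tobytes() + record.clean_samples.tobytes()


def save_weights(weights, path) -> Path:
    """Serialize IATWeights or PositionWeights to <path>.npz + <path>.json."""
    path = Path(path)
    arrays = {f"p{i}": a for i, a in enumerate(weights.arrays)}
    if hasattr(weights, "reference"):
        arrays["reference"] = weights.reference
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {"config": dataclasses.asdict(weights.config),
            "loss_log": list(weights.loss_log), "seed": int(weights.seed),
            "kind": type(weights).__name__}
    if hasattr(weights, "trained"):
        meta["trained"] = bool(weights.trained)
    if hasattr(weights, "train_accuracy"):
        meta["train_accuracy"] = float(weights.train_accuracy)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path.with_suffix(".npz")


def load_weights(path):
    from .iat import IATConfig, IATWeights
    from .position import PositionNetConfig, PositionWeights
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path.with_suffix(".npz"))
    n = len([k for k in data.files if k.startswith("p")])
    arrays = [data[f"p{i}"] for i in range(n)]
    if meta["kind"] == "IATWeights":
        return IATWeights(config=IATConfig(**meta["config"]), arrays=arrays,
                          loss_log=meta["loss_log"], seed=meta["seed"],
                          train_accuracy=meta.get("train_accuracy", float("nan")))
    return PositionWeights(config=PositionNetConfig(**meta["config"]),
                           arrays=arrays, reference=data["reference"],
                           loss_log=meta["loss_log"], seed=meta["seed"],
                           trained=meta.get("trained", True))
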