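"""Wear-position assessment: FC embedding -> 1-D CNN -> GRU summary,
a discriminator against the standard-position reference, a 3-way orientation
classifier, and a rotation adjustment suggestion.

The record is cut into 1-second chunks; each chunk is projected into a
higher-dimensional space by a fully connected layer, a 1-D convolution
extracts relationships between neighbouring chunks, and a GRU summarizes the
sequence into one vector. Two heads read that summary: a softmax orientation
classifier over {O0, O120, O240}, and a discriminator that scores — against
the encoded reference vector of the standard placement — whether the summary
meets the placement tolerance. Training is adversarial in the GAN sense:
the discriminator learns to separate standard-position summaries (real) from
misplaced ones (fake); because the discriminator is a *verifier*, its loss
also shapes the feature extractor (no gradient reversal), sharpening the
separation rather than hiding it.

The patch geometry admits only three stable placements, so the adjustment is
the group-inverse rotation in {0, -120, +120} degrees mapping the predicted
orientation back to O0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import GRU, Adam, Conv1dSeq, Linear, Tensor, cross_entropy
from .nn.layers import Module
from .synth import ORIENTATION_LABELS


def _softmax64(z: np.ndarray) -> np.ndarray:
    """Row softmax in float64 so probabilities sum to 1 at double precision."""
    z = z.astype(np.float64)
    z -= z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)

ORIENT_TO_INT = {o: i for i, o in enumerate(ORIENTATION_LABELS)}
#: Rotation (degrees) that maps each orientation back to the standard one.
ADJUSTMENT_DEG = {"O0": 0, "O120": -120, "O240": 120}


@dataclass(frozen=True)
class PositionNetConfig:
    input_len: int = 2500        # samples (10 s at 250 Hz)
    chunk_len: int = 250         # samples per FC-embedded chunk (1 s)
    fc_dim: int = 32
    conv_channels: int = 32
    conv_kernel: int = 3
    gru_hidden: int = 32
    tolerance_threshold: float = 0.5
    adversarial_weight: float = 1.0
    epochs: int = 30
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.tolerance_threshold < 1.0:
            raise ValueError("tolerance_threshold must lie in (0, 1)")
        if self.input_len % self.chunk_len:
            raise ValueError("chunk_len must divide input_len")


@dataclass
class PositionAssessment:
    orientation: str
    probabilities: np.ndarray          # 3-vector over (O0, O120, O240)
    within_tolerance: bool
    discriminator_score: float
    adjustment_deg: int

    def to_dict(self) -> dict:
        return {"orientation": self.orientation,
                "probabilities": [float(p) for p in self.probabilities],
                "within_tolerance": bool(self.within_tolerance),
                "discriminator_score": float(self.discriminator_score),
                "adjustment_deg": int(self.adjustment_deg)}


@dataclass
class PositionWeights:
    config: PositionNetConfig
    arrays: list
    reference: np.ndarray              # encoded standard-position summary
    loss_log: list = field(default_factory=list)
    seed: int = 0
    trained: bool = False


class PositionNet(Module):
    def __init__(self, config: PositionNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.fc = Linear(c.chunk_len, c.fc_dim, rng)
        self.conv = Conv1dSeq(c.fc_dim, c.conv_channels, c.conv_kernel, rng)
        self.gru = GRU(c.conv_channels, c.gru_hidden, rng)
        self.cls_head = Linear(c.gru_hidden, 3, rng)
        self.disc1 = Linear(2 * c.gru_hidden, c.gru_hidden, rng)
        self.disc2 = Linear(c.gru_hidden, 1, rng)

    # -- forward pieces ---------------------------------------------------
    def embed(self, windows: np.ndarray) -> Tensor:
        """(B, L) -> (B, n_chunks, fc_dim) FC embedding of 1 s chunks."""
        c = self.config
        B, L = np.atleast_2d(windows).shape
        if L != c.input_len:
            raise ValueError(f"expected windows of {c.input_len} samples, got {L}")
        x = np.atleast_2d(windows).reshape(B, L // c.chunk_len, c.chunk_len)
        return self.fc(Tensor(x)).tanh()

    def summarize(self, embedded: Tensor, lengths: np.ndarray = None) -> Tensor:
        """Conv over the chunk sequence, then GRU; final hidden state."""
        if embedded.shape[1] < 1:
            raise ValueError("empty embedding sequence")
        feats = self.conv(embedded).tanh()
        return self.gru(feats, lengths=lengths)

    def summary(self, windows: np.ndarray) -> Tensor:
        return self.summarize(self.embed(windows))

    def discriminate(self, summary: Tensor, reference: np.ndarray) -> Tensor:
        """Probability in (0, 1) that the summary lies on the
        standard-position manifold."""
        B = summary.shape[0]
        if reference.shape[-1] != summary.shape[-1]:
            raise ValueError("summary/reference dimension mismatch")
        ref = Tensor(np.broadcast_to(reference, (B, reference.shape[-1])).copy())
        from .nn import concat
        h = self.disc1(concat([summary, ref], axis=1)).tanh()
        return self.disc2(h).sigmoid()

    def classify_logits(self, summary: Tensor) -> Tensor:
        return self.cls_head(summary)


# ---------------------------------------------------------------------------


def train_position_net(records, orientation_labels,
                       config: PositionNetConfig = PositionNetConfig(),
                       windows: np.ndarray = None, verbose: bool = False):
    """Joint training: orientation cross-entropy + adversarial
    real-vs-misplaced discriminator loss. Returns (net, PositionWeights)."""
    y = np.asarray([ORIENT_TO_INT[o] for o in orientation_labels])
    if np.unique(y).size < 3:
        raise ValueError("all three orientations must be present")
    X = prepare_windows(records, config.input_len) if windows is None else windows
    net = PositionNet(config)
    opt = Adam(net.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    loss_log = []
    reference = np.zeros(config.gru_hidden)
    for epoch in range(config.epochs):
        order = rng.permutation(len(X))
        epoch_loss = 0.0
        ref_sum = np.zeros(config.gru_hidden)
        ref_n = 0
        for start in range(0, len(X), config.batch_size):
            batch = order[start:start + config.batch_size]
            summary = net.summary(X[batch])
            logits = net.classify_logits(summary)
            loss = cross_entropy(logits, y[batch])
            score = net.discriminate(summary, reference)
            real = (y[batch] == 0).astype(float)[:, None]
            eps = 1e-7
            bce = -(Tensor(real) * (score + eps).log()
                    + Tensor(1.0 - real) * (1.0 - score + eps).log()).mean()
            loss = loss + config.adversarial_weight * bce
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
            std = summary.data[y[batch] == 0]
            ref_sum += std.sum(axis=0)
            ref_n += len(std)
        if ref_n:
            reference = ref_sum / ref_n
        loss_log.append(epoch_loss / len(X))
        if verbose:
            print(f"epoch {epoch + 1:3d}  loss {loss_log[-1]:.4f}")
    # freeze the reference as the mean standard-position summary under the
    # final weights
    std_idx = np.flatnonzero(y == 0)
    reference = net.summary(X[std_idx]).data.mean(axis=0)
    weights = PositionWeights(config=config, arrays=net.state_arrays(),
                              reference=reference, loss_log=loss_log,
                              seed=config.seed, trained=True)
    return net, weights


def net_from_weights(weights: PositionWeights) -> PositionNet:
    if not weights.trained:
        raise ValueError("model not ready: weights are untrained")
    net = PositionNet(weights.config)
    net.load_arrays(weights.arrays)
    return net


def prepare_windows(records, input_len: int = 2500) -> np.ndarray:
    """Records -> fixed-length raw-mV windows.

    Deliberately *not* z-scored: baseline offset, amplitude scale and
    polarity are exactly the cues a misplaced patch leaves in the trace.
    """
    out = []
    for r in records:
        x = np.asarray(r.samples, dtype=float)[:input_len]
        if x.size < input_len:
            raise ValueError("record shorter than the assessment window")
        out.append(x)
    return np.stack(out).astype(np.float32)


def classify_position(net: PositionNet, weights: PositionWeights,
                      window: np.ndarray) -> PositionAssessment:
    """Full assessment of one window: orientation, tolerance, adjustment."""
    if not weights.trained:
        raise ValueError("model not ready: weights are untrained")
    summary = net.summary(np.atleast_2d(window))
    probs = _softmax64(net.classify_logits(summary).data)[0]
    score = float(net.discriminate(summary, weights.reference).data[0, 0])
    orient = ORIENTATION_LABELS[int(np.argmax(probs))]
    return PositionAssessment(
        orientation=orient, probabilities=probs,
        within_tolerance=score >= weights.config.tolerance_threshold,
        discriminator_score=score,
        adjustment_deg=ADJUSTMENT_DEG[orient])


def discriminator_score(net: PositionNet, weights: PositionWeights,
                        windows: np.ndarray) -> np.ndarray:
    summary = net.summary(np.atleast_2d(windows))
    return net.discriminate(summary, weights.reference).data[:, 0]


def evaluate_position(net: PositionNet, weights: PositionWeights,
                      records, orientation_labels,
                      windows: np.ndarray = None) -> dict:
    y = np.asarray([ORIENT_TO_INT[o] for o in orientation_labels])
    X = prepare_windows(records, weights.config.input_len) if windows is None else windows
    summary = net.summary(X)
    probs = _softmax64(net.classify_logits(summary).data)
    pred = np.argmax(probs, axis=1)
    scores = net.discriminate(summary, weights.reference).data[:, 0]
    conf = np.zeros((3, 3), dtype=int)
    for t, p in zip(y, pred):
        conf[t, p] += 1
    return {"accuracy": float(np.mean(pred == y)), "confusion": conf,
            "scores": scores, "predictions": pred}
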