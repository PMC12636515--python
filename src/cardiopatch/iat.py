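"""Interpretable attention transformer (IAT) for 4-class ECG classification.

The input window is cut into non-overlapping slices; each slice passes
through a 1-D convolution (local feature extraction) and a linear projection
into the embedding space. A learned CLS token is prepended, learned
positional encodings are added, and pre-norm multi-head self-attention
encoder blocks produce the encoded representations and attention score
matrices. By default slice tokens attend only themselves (the CLS row is
global), so every token representation stays strictly local to its 0.2 s of
signal. Classification uses a class-query attention readout: one learned
query per class in {NR, AR, AH, MI} scores the token representations, and
each logit is a linear read of its class's attention-pooled context — so
the predicted class's attention row must sit on the tokens whose content
supports that diagnosis. That row, spread over the token sample spans, is
the per-sample saliency map (encoder CLS-row and attention-rollout readings
are available as alternatives). Rationale and failure modes of the simpler
designs are documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import preprocess
from .nn import (Adam, Linear, Tensor, TransformerBlock, cross_entropy,
                 init_uniform)
from .nn.layers import Module
from .synth import CLASS_LABELS

LABEL_TO_INT = {c: i for i, c in enumerate(CLASS_LABELS)}


@dataclass(frozen=True)
class IATConfig:
    slice_len: int = 50          # samples per token (0.2 s at 250 Hz)
    embed_dim: int = 64
    n_heads: int = 4
    n_layers: int = 2
    mlp_dim: int = 128
    dropout: float = 0.1
    n_classes: int = 4
    conv_kernel: int = 7
    conv_channels: int = 8
    input_len: int = 2500        # samples per diagnostic window (10 s at 250 Hz)
    epochs: int = 30
    batch_size: int = 32
    lr: float = 1e-3
    #: weight of the CLS-attention entropy penalty; a sparsity prior that
    #: concentrates the global aggregation on informative tokens, which is
    #: what makes the attention map read as a clinical-evidence highlight
    attn_entropy_weight: float = 0.1
    #: slice tokens attend only their +/- this-many-token neighbourhood;
    #: the CLS token alone aggregates globally. Keeps token representations
    #: local, so the CLS attention row must sit on the evidence itself
    #: rather than on an arbitrary carrier of globally mixed information.
    #: 0 disables the band (full self-attention everywhere).
    local_attn_window: int = 0
    seed: int = 0
    #: "readout" = predicted class's class-query attention row (default);
    #: "cls" = final-layer CLS row, head-averaged; "rollout" = attention
    #: rollout through the encoder layers
    saliency_method: str = "readout"

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.n_classes != 4:
            raise ValueError("the diagnosis task is 4-class")

    @property
    def n_tokens(self) -> int:
        return self.input_len // self.slice_len


@dataclass
class TokenSequence:
    tokens: np.ndarray           # (T+1, embed_dim), CLS first
    slice_spans: list            # per non-CLS token: (start, end)
    dropped_samples: int = 0


@dataclass
class AttentionSaliency:
    per_sample: np.ndarray       # >= 0, sums to 1, constant within slices


@dataclass
class IATWeights:
    config: IATConfig
    arrays: list                 # all trainable parameters, model order
    loss_log: list = field(default_factory=list)
    seed: int = 0
    train_accuracy: float = float("nan")


class IATModel(Module):
    def __init__(self, config: IATConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        conv_pos = c.slice_len - c.conv_kernel + 1
        self.conv_W = init_uniform(rng, c.conv_kernel, c.conv_channels,
                                   fan_in=c.conv_kernel)
        self.conv_b = Tensor(np.zeros(c.conv_channels), requires_grad=True)
        self.proj = Linear(conv_pos * c.conv_channels, c.embed_dim, rng)
        self.cls = Tensor(rng.standard_normal(c.embed_dim) * 0.02,
                          requires_grad=True)
        self.pos = Tensor(rng.standard_normal((c.n_tokens + 1, c.embed_dim)) * 0.02,
                          requires_grad=True)
        self.blocks = [TransformerBlock(c.embed_dim, c.n_heads, c.mlp_dim, rng)
                       for _ in range(c.n_layers)]
        self.ln_g = Tensor(np.ones(c.embed_dim), requires_grad=True)
        self.ln_b = Tensor(np.zeros(c.embed_dim), requires_grad=True)
        # class-query attention readout: one learned query per class scores
        # the slice tokens; each logit is a linear read of its class's
        # attention-pooled context. The class row must therefore sit on
        # tokens whose content supports that class — the attention matrix
        # is the diagnosis evidence by construction.
        self.class_queries = Tensor(
            rng.standard_normal((c.n_classes, c.embed_dim)) * 0.2,
            requires_grad=True)
        self.readout_k = Linear(c.embed_dim, c.embed_dim, rng)
        self.readout_v = Linear(c.embed_dim, c.embed_dim, rng)
        self.head = Linear(c.embed_dim, c.n_classes, rng)

    # -- tokenization ----------------------------------------------------
    def _slice_batch(self, windows: np.ndarray):
        """(B, L) -> im2col (B, S, P, k) constant plus spans; remainder samples
        beyond S*slice_len are dropped."""
        c = self.config
        B, L = windows.shape
        n_slices = L // c.slice_len
        if n_slices < 1:
            raise ValueError("window shorter than one slice")
        dropped = L - n_slices * c.slice_len
        x = windows[:, :n_slices * c.slice_len].reshape(B, n_slices, c.slice_len)
        P = c.slice_len - c.conv_kernel + 1
        cols = np.stack([x[:, :, j:j + P] for j in range(c.conv_kernel)], axis=-1)
        # cols: (B, S, P, k)
        spans = [(i * c.slice_len, (i + 1) * c.slice_len) for i in range(n_slices)]
        return cols, spans, dropped

    def embed(self, windows: np.ndarray) -> Tensor:
        """(B, L) -> (B, T+1, E) token embeddings with CLS and positions."""
        cols, spans, _ = self._slice_batch(windows)
        B, S = cols.shape[:2]
        feats = (Tensor(cols) @ self.conv_W + self.conv_b).relu()
        feats = feats.reshape(B, S, -1)
        tok = self.proj(feats)
        cls = self.cls.reshape(1, 1, -1) * Tensor(np.ones((B, 1, 1)))
        from .nn import concat
        tokens = concat([cls, tok], axis=1)
        return tokens + self.pos.reshape(1, S + 1, -1)

    def tokenize(self, window: np.ndarray) -> TokenSequence:
        """Deterministic token sequence for a single window."""
        cols, spans, dropped = self._slice_batch(window[None, :])
        tokens = self.embed(window[None, :]).data[0]
        return TokenSequence(tokens=tokens, slice_spans=spans,
                             dropped_samples=dropped)

    def _attn_mask(self, n_tokens: int):
        """Local-band mask: slice tokens see +/- local_attn_window
        neighbours (never the CLS token, so global information cannot be
        re-broadcast into them); the CLS row is unrestricted."""
        w = self.config.local_attn_window
        if w < 0:
            return None
        T = n_tokens
        mask = np.zeros((T, T), dtype=bool)
        mask[0, :] = True
        idx = np.arange(1, T)
        for i in idx:
            lo = max(1, i - w)
            mask[i, lo:min(T, i + w + 1)] = True
        return mask

    # -- forward ---------------------------------------------------------
    def forward(self, windows: np.ndarray, dropout_rng: np.random.Generator = None,
                return_attn_tensor: bool = False):
        """Returns (logits Tensor (B, 4), attention (layers, B, heads, T+1, T+1)).

        With ``return_attn_tensor`` the class-readout attention rows
        (B, n_classes, T) are also returned as a live graph node (for the
        entropy penalty in training).
        """
        c = self.config
        x = self.embed(windows)
        mask = self._attn_mask(x.shape[1])
        attns = []
        for block in self.blocks:
            masks = None
            if dropout_rng is not None and c.dropout > 0:
                keep = 1.0 - c.dropout
                masks = [Tensor(dropout_rng.binomial(1, keep, size=x.shape) / keep)
                         for _ in range(2)]
            x, attn_t = block(x, dropout_mask=masks, attn_mask=mask)
            attns.append(attn_t.data)
        from .nn import layer_norm, softmax as nn_softmax
        x = layer_norm(x, self.ln_g, self.ln_b)
        tokens = x[:, 1:, :]
        k = self.readout_k(tokens)                       # (B, T, E)
        v = self.readout_v(tokens)
        scores = (k @ self.class_queries.transpose(1, 0)) \
            * (1.0 / np.sqrt(c.embed_dim))               # (B, T, C)
        rows = nn_softmax(scores.transpose(0, 2, 1), axis=-1)  # (B, C, T)
        ctx = rows @ v                                   # (B, C, E)
        logits = (ctx * self.head.W.transpose(1, 0)).sum(axis=-1) + self.head.b
        self.last_readout = rows.data.copy()
        if return_attn_tensor:
            return logits, np.stack(attns), rows
        return logits, np.stack(attns)

    def readout_rows(self, window: np.ndarray) -> np.ndarray:
        """(n_classes, n_tokens) class-evidence attention rows."""
        _, _, rows = self.forward(window[None, :], return_attn_tensor=True)
        return rows.data[0]

    def predict_proba(self, windows: np.ndarray,
                      chunk: int = 64) -> np.ndarray:
        """Class probabilities; softmax in float64 so rows sum to 1 at
        double precision. Large batches are processed in chunks."""
        windows = np.atleast_2d(windows)
        out = []
        for start in range(0, len(windows), chunk):
            logits, _ = self.forward(windows[start:start + chunk])
            z = logits.data.astype(np.float64)
            z -= z.max(axis=-1, keepdims=True)
            e = np.exp(z)
            out.append(e / e.sum(axis=-1, keepdims=True))
        return np.concatenate(out, axis=0)

    def attention_tensor(self, window: np.ndarray) -> np.ndarray:
        """(n_layers, n_heads, T+1, T+1) for a single window."""
        _, attns = self.forward(window[None, :])
        return attns[:, 0]


# ---------------------------------------------------------------------------
# functional surface


def classify(model: IATModel, windows: np.ndarray) -> np.ndarray:
    """Class probabilities, rows summing to 1, classes ordered as
    (NR, AR, AH, MI)."""
    return model.predict_proba(np.atleast_2d(windows))


def saliency(attn: np.ndarray, spans: list, n_samples: int,
             method: str = "cls") -> AttentionSaliency:
    """Per-sample attention saliency from an attention tensor.

    ``cls``: final-layer CLS row, head-averaged, CLS self-score dropped,
    renormalized. ``rollout``: multiply head-averaged (A + I)/2 across
    layers, then read the CLS row. Mass is spread uniformly over each
    token's sample span and normalized to sum to 1.
    """
    if method == "cls":
        row = attn[-1].mean(axis=0)[0, 1:]
    elif method == "rollout":
        layers = attn.mean(axis=1)  # (n_layers, T+1, T+1)
        n = layers.shape[-1]
        rollout = np.eye(n)
        for A in layers:
            A_hat = (A + np.eye(n)) / 2.0
            A_hat = A_hat / A_hat.sum(axis=-1, keepdims=True)
            rollout = A_hat @ rollout
        row = rollout[0, 1:]
    else:
        raise ValueError(f"unknown saliency method {method!r}")
    row = np.maximum(row, 0.0)
    row = row / row.sum()
    per_sample = np.zeros(n_samples)
    for weight, (on, off) in zip(row, spans):
        per_sample[on:off] = weight / (off - on)
    total = per_sample.sum()
    if total > 0:
        per_sample /= total
    return AttentionSaliency(per_sample=per_sample)


def saliency_for_window(model: IATModel, window: np.ndarray,
                        method: str = None) -> AttentionSaliency:
    method = method or model.config.saliency_method
    seq = model.tokenize(window)
    if method == "readout":
        logits, _, rows = model.forward(window[None, :],
                                        return_attn_tensor=True)
        row = rows.data[0, int(np.argmax(logits.data[0]))]
        row = np.maximum(row.astype(float), 0.0)
        row /= row.sum()
        per_sample = np.zeros(len(window))
        for weight, (on, off) in zip(row, seq.slice_spans):
            per_sample[on:off] = weight / (off - on)
        per_sample /= per_sample.sum()
        return AttentionSaliency(per_sample=per_sample)
    attn = model.attention_tensor(window)
    return saliency(attn, seq.slice_spans, len(window), method=method)


# ---------------------------------------------------------------------------
# training & evaluation


def prepare_window(record, input_len: int = 2500) -> np.ndarray:
    """Record -> model-ready window: filter chain, then a *robust* per-window
    standardization (median centre, SD scale).

    Centre and scale follow electrocardiographic convention: levels are
    measured relative to the TP-segment isoelectric line (the flat interval
    between a T wave and the next P wave, located from the detected R
    peaks), and amplitudes relative to the median detected R-peak height.
    Both references are robust to localized pathology — an elevated ST
    segment or an enlarged P wave cannot move them — so a class signature
    cannot leak into global statistics and be read off anywhere in the
    window; the evidence stays where the pathology is, which is what makes
    the attention map meaningful. No baseline-estimation filter is applied:
    estimated baselines absorb part of an enlarged wave and leave
    class-dependent dips beside it. Residual wander stays in the input as
    class-independent noise. Fallback (fewer than 3 detected beats): global
    median centre, 99.8th-percentile scale.
    """
    from scipy import signal as sps

    from . import vitals
    spec = preprocess.FilterSpec()
    x = preprocess.notch_filter(record.samples, record.fs, spec)
    sos = sps.butter(spec.filter_order, spec.band_high, btype="lowpass",
                     fs=record.fs, output="sos")
    x = sps.sosfiltfilt(sos, x)[:input_len]
    if x.size < input_len:
        raise ValueError("record shorter than the diagnostic window")
    try:
        rpeaks = vitals.pan_tompkins(x, record.fs).indices
    except ValueError:
        rpeaks = np.empty(0, dtype=int)
    if rpeaks.size >= 3:
        rr = float(np.median(np.diff(rpeaks)))
        tp_mask = np.zeros(x.size, dtype=bool)
        for r in rpeaks:
            tp_mask[int(r + 0.55 * rr):int(r + 0.68 * rr)] = True
        centre = float(np.median(x[tp_mask])) if tp_mask.any() else float(np.median(x))
        scale = float(np.median(np.abs(x[rpeaks] - centre)))
    else:
        centre = float(np.median(x))
        scale = float(np.percentile(np.abs(x - centre), 99.8))
    if scale == 0:
        return np.zeros(x.size, dtype=np.float32)
    return ((x - centre) / scale).astype(np.float32)


def prepare_dataset(records, input_len: int = 2500) -> np.ndarray:
    return np.stack([prepare_window(r, input_len) for r in records])


def train(records, labels, config: IATConfig = IATConfig(),
          windows: np.ndarray = None, verbose: bool = False):
    """Train the IAT; returns (model, IATWeights).

    ``labels`` are class-name strings. Cross-entropy, Adam, fixed epoch
    budget, seeded init and batch order — two runs with the same seed produce
    identical weights.
    """
    y = np.asarray([LABEL_TO_INT[l] for l in labels])
    if np.unique(y).size < 2:
        raise ValueError("training requires at least two classes present")
    X = prepare_dataset(records, config.input_len) if windows is None else windows
    model = IATModel(config)
    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    drop_rng = np.random.default_rng(config.seed + 2)
    loss_log = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(X))
        epoch_loss = 0.0
        for start in range(0, len(X), config.batch_size):
            batch = order[start:start + config.batch_size]
            logits, _, rows = model.forward(X[batch], dropout_rng=drop_rng,
                                            return_attn_tensor=True)
            loss = cross_entropy(logits, y[batch])
            if config.attn_entropy_weight > 0:
                # sparsity prior on every class-readout row — each class's
                # evidence should be a few tokens, not a uniform mix
                ent = -(rows * (rows + 1e-12).log()).sum(axis=-1).mean()
                loss = loss + config.attn_entropy_weight * ent
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
        loss_log.append(epoch_loss / len(X))
        if verbose:
            print(f"epoch {epoch + 1:3d}  loss {loss_log[-1]:.4f}")
    pred = np.argmax(model.predict_proba(X), axis=1)
    weights = IATWeights(config=config, arrays=model.state_arrays(),
                         loss_log=loss_log, seed=config.seed,
                         train_accuracy=float(np.mean(pred == y)))
    return model, weights


def model_from_weights(weights: IATWeights) -> IATModel:
    model = IATModel(weights.config)
    model.load_arrays(weights.arrays)
    return model


def evaluate(model: IATModel, records, labels, windows: np.ndarray = None):
    """Held-out accuracy, per-class recall and 4x4 confusion matrix.

    Returns a dict with ``accuracy``, ``recall`` (per class), ``confusion``
    (raw counts, rows = truth) and ``confusion_normalized`` (row-stochastic).
    """
    if len(labels) == 0:
        raise ValueError("empty evaluation set")
    y = np.asarray([LABEL_TO_INT[l] for l in labels])
    X = prepare_dataset(records, model.config.input_len) if windows is None else windows
    pred = np.argmax(model.predict_proba(X), axis=1)
    k = model.config.n_classes
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(y, pred):
        conf[t, p] += 1
    row_sums = conf.sum(axis=1, keepdims=True)
    norm = np.divide(conf, row_sums, where=row_sums > 0,
                     out=np.zeros((k, k)))
    recall = {CLASS_LABELS[i]: (float(norm[i, i]) if row_sums[i, 0] else float("nan"))
              for i in range(k)}
    return {"accuracy": float(np.mean(pred == y)), "recall": recall,
            "confusion": conf, "confusion_normalized": norm,
            "predictions": pred}
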