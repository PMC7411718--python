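"""Identification networks: CNN and LSTM branches, FC softmax head, ensemble.

Both networks share one layout: an independent branch per sensing modality
(pressure / acceleration / rotation), branch outputs concatenated into one
feature vector, then a fully connected head (256 ReLU units, dropout with
keep probability 0.7, dense softmax over participants).

CNN branch: three 1-D convolutions over time (32, 64, 128 filters, kernel
length 20, stride 1, 'same' padding so the time dimension k*d is preserved),
each followed by ReLU, then flattened. For d=87, k=1 the per-branch feature
maps are 87x32, 87x64, 87x128 and the flattened vector has 87*128 entries.

RNN branch: two LSTM layers of 64 units with hard-sigmoid gate activations
and recurrent dropout 0.2; the first returns its full (k*d)x64 output
sequence, the second only its final 64-vector.

The ensemble is the elementwise mean of the two networks' softmax outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .standardize import MODALITIES, StandardSample, scale_modality

MODALITY_INPUT_WIDTH = {"p": 16, "a": 6, "r": 6}


@dataclass
class ModelConfig:
    """Architecture and training configuration.

    The architectural fields carry the published defaults; the training
    fields (optimizer, rate, batch size, epochs) are this package's own
    choices since no training regimen is prescribed for the architecture.
    """

    modalities: tuple[str, ...] = ("p", "a", "r")
    d: int = 87
    k: int = 1
    n_classes: int = 2
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    conv_kernel_len: int = 20
    lstm_units: int = 64
    lstm_recurrent_dropout: float = 0.2
    fc_units: int = 256
    fc_keep_prob: float = 0.7
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    early_stop_patience: int = 3
    early_stop_min_delta: float = 1e-3

    def __post_init__(self) -> None:
        mods = tuple(self.modalities)
        if not mods or any(m not in MODALITIES for m in mods):
            raise ValueError("modalities must be a non-empty subset of {'p','a','r'}")
        if len(set(mods)) != len(mods):
            raise ValueError("duplicate modality")
        # canonical order p, a, r regardless of how the subset was given
        self.modalities = tuple(m for m in MODALITIES if m in mods)
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not 1 <= self.k <= 4:
            raise ValueError("k must be in 1..4")
        if self.d < 2:
            raise ValueError("d must be at least 2")


@dataclass
class SoftmaxOutput:
    """A probability vector over participants."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1:
            raise ValueError("probs must be a vector")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("probs must be non-negative and sum to 1")


class FCHead:
    """Dense(256) + ReLU -> dropout (keep 0.7, training only) -> dense softmax."""

    def __init__(self, in_dim: int, cfg: ModelConfig, rng: np.random.Generator):
        self.fc1 = nn.Dense(in_dim, cfg.fc_units, rng)
        self.relu = nn.ReLU()
        self.drop = nn.Dropout(cfg.fc_keep_prob)
        self.fc2 = nn.Dense(cfg.fc_units, cfg.n_classes, rng)
        self.layers = [self.fc1, self.relu, self.drop, self.fc2]
        self.params = [p for layer in self.layers for p in layer.params]

    def logits(self, features, training=False, rng=None):
        out = features
        for layer in self.layers:
            out = layer.forward(out, training=training, rng=rng)
        return out

    def hidden(self, features):
        """Post-ReLU activations of the 256-unit layer (inference mode)."""
        return self.relu.forward(self.fc1.forward(features))

    def __call__(self, features, training=False, rng=None):
        return nn.softmax(self.logits(features, training=training, rng=rng))

    def backward(self, dlogits):
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d


class BranchedClassifier:
    """Per-modality branches -> concatenated features -> FC softmax head."""

    kind = "base"

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.branches: dict[str, list[nn.Layer]] = {
            m: self._build_branch(MODALITY_INPUT_WIDTH[m], cfg, rng)
            for m in cfg.modalities
        }
        self.head = FCHead(self._feature_len(cfg), cfg, rng)
        self.params = [
            p
            for m in cfg.modalities
            for layer in self.branches[m]
            for p in layer.params
        ] + self.head.params
        self.classes_: list[str] | None = None
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}

    # subclasses define the branch stack and its output width
    def _build_branch(self, in_ch, cfg, rng):  # pragma: no cover - abstract
        raise NotImplementedError

    def _feature_len(self, cfg):  # pragma: no cover - abstract
        raise NotImplementedError

    def _branch_forward(self, m, x, training, rng):
        out = x
        for layer in self.branches[m]:
            out = layer.forward(out, training=training, rng=rng)
        return out

    def forward_logits(self, inputs: dict[str, np.ndarray], training=False, rng=None):
        feats = []
        self._splits = []
        for m in self.cfg.modalities:
            f = self._branch_forward(m, inputs[m], training, rng)
            feats.append(f)
            self._splits.append(f.shape[1])
        concat = np.concatenate(feats, axis=1)
        return self.head.logits(concat, training=training, rng=rng)

    def backward(self, dlogits):
        dconcat = self.head.backward(dlogits)
        offset = 0
        for m, width in zip(self.cfg.modalities, self._splits):
            d = dconcat[:, offset : offset + width]
            offset += width
            for layer in reversed(self.branches[m]):
                d = layer.backward(d)

    def predict_proba(self, inputs: dict[str, np.ndarray], batch_size=256):
        n = next(iter(inputs.values())).shape[0]
        out = []
        for lo in range(0, n, batch_size):
            batch = {m: x[lo : lo + batch_size] for m, x in inputs.items()}
            out.append(nn.softmax(self.forward_logits(batch, training=False)))
        return np.concatenate(out, axis=0)

    def features_256(self, inputs: dict[str, np.ndarray], batch_size=256):
        """Activations of the 256-unit FC layer, for embedding plots."""
        n = next(iter(inputs.values())).shape[0]
        out = []
        for lo in range(0, n, batch_size):
            batch = {m: x[lo : lo + batch_size] for m, x in inputs.items()}
            feats = [
                self._branch_forward(m, batch[m], False, None)
                for m in self.cfg.modalities
            ]
            out.append(self.head.hidden(np.concatenate(feats, axis=1)))
        return np.concatenate(out, axis=0)


class GaitCNN(BranchedClassifier):
    kind = "cnn"

    def _build_branch(self, in_ch, cfg, rng):
        f1, f2, f3 = cfg.conv_filters
        k = cfg.conv_kernel_len
        return [
            nn.Conv1D(in_ch, f1, k, rng),
            nn.ReLU(),
            nn.Conv1D(f1, f2, k, rng),
            nn.ReLU(),
            nn.Conv1D(f2, f3, k, rng),
            nn.ReLU(),
            nn.Flatten(),
        ]

    def _feature_len(self, cfg):
        return cfg.k * cfg.d * cfg.conv_filters[-1] * len(cfg.modalities)


class GaitRNN(BranchedClassifier):
    kind = "rnn"

    def _build_branch(self, in_ch, cfg, rng):
        return [
            nn.LSTM(
                in_ch,
                cfg.lstm_units,
                rng,
                return_sequences=True,
                recurrent_dropout=cfg.lstm_recurrent_dropout,
            ),
            nn.LSTM(
                cfg.lstm_units,
                cfg.lstm_units,
                rng,
                return_sequences=False,
                recurrent_dropout=cfg.lstm_recurrent_dropout,
            ),
        ]

    def _feature_len(self, cfg):
        return cfg.lstm_units * len(cfg.modalities)


def build_cnn(cfg: ModelConfig) -> GaitCNN:
    return GaitCNN(cfg)


def build_rnn(cfg: ModelConfig) -> GaitRNN:
    return GaitRNN(cfg)


def ensemble_predict(p_cnn: np.ndarray, p_rnn: np.ndarray) -> np.ndarray:
    """Averaging ensemble: the elementwise mean of the two softmax outputs."""
    a, b = np.asarray(p_cnn, dtype=float), np.asarray(p_rnn, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"softmax shapes differ: {a.shape} vs {b.shape}")
    return 0.5 * (a + b)


def stack_features(
    samples: list[StandardSample], modalities: tuple[str, ...]
) -> tuple[dict[str, np.ndarray], np.ndarray, list[str]]:
    """Stack StandardSamples into scaled model inputs.

    Returns ``(inputs, labels, classes)`` where ``inputs[m]`` is
    (N, k*d, w*2) float32 in model units and ``labels`` are integer class
    indices into the sorted participant list ``classes``.
    """
    if not samples:
        raise ValueError("no samples")
    classes = sorted({s.participant_id for s in samples})
    class_index = {c: i for i, c in enumerate(classes)}
    labels = np.array([class_index[s.participant_id] for s in samples])
    inputs = {
        m: np.stack([scale_modality(s.modality(m), m) for s in samples])
        for m in modalities
    }
    return inputs, labels, classes


def train_model(
    model: BranchedClassifier,
    train_samples: list[StandardSample],
    cfg: ModelConfig | None = None,
) -> BranchedClassifier:
    """Train in place: Adam on softmax cross-entropy, mini-batches of 32.

    Runs for ``cfg.epochs`` epochs at most, stopping early when the epoch
    loss plateaus (no improvement over ``early_stop_min_delta`` for
    ``early_stop_patience`` epochs) or training accuracy saturates.
    Deterministic given ``cfg.seed``: it drives weight init (at build),
    batch shuffling and dropout masks. Every class must be represented.
    """
    cfg = cfg or model.cfg
    inputs, labels, classes = stack_features(train_samples, cfg.modalities)
    if len(np.unique(labels)) != cfg.n_classes:
        raise ValueError(
            f"training set covers {len(classes)} classes, config expects "
            f"{cfg.n_classes}; every class needs at least one sample"
        )
    model.classes_ = classes
    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    n = labels.size
    best_loss = np.inf
    stale = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        correct = 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            batch = {m: x[idx] for m, x in inputs.items()}
            y = labels[idx]
            opt.zero_grad()
            logits = model.forward_logits(batch, training=True, rng=rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, y)
            model.backward(dlogits)
            opt.step()
            total_loss += loss * idx.size
            correct += int((logits.argmax(axis=1) == y).sum())
        epoch_loss = total_loss / n
        epoch_acc = correct / n
        model.history["loss"].append(epoch_loss)
        model.history["accuracy"].append(epoch_acc)
        if epoch_loss < best_loss - cfg.early_stop_min_delta:
            best_loss = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
        if epoch_acc >= 0.9995 and epoch_loss < 0.02:
            break
    return model


def predict_samples(
    model: BranchedClassifier, samples: list[StandardSample]
) -> np.ndarray:
    """Softmax probabilities for a list of samples, in the model's class order."""
    if model.classes_ is None:
        raise ValueError("model is not fitted")
    inputs, _, _ = stack_features(samples, model.cfg.modalities)
    return model.predict_proba(inputs)
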