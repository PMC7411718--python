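"""Monte Carlo cross-validation, experiment runs, and embedding export.

Three split protocols are supported, all stratified per participant so
every class appears in both halves (training is impossible otherwise):

- ``MCCV30``: 30% of all samples held out for testing, the rest trained on.
- ``MCCV50``: floor(N/2) samples for testing, the rest trained on.
- ``SubMCCV50``: equal-size train and test sets drawn from a proper subset
  of the data (per participant, 2*floor(0.42*n) samples split evenly),
  about 84% of the cohort in total — the reduced-data protocol.

An experiment repeats the chosen protocol R times; per repeat the CNN and
RNN are trained independently on the training half, their softmax outputs
are stored on the test half, and the ensemble accuracy is computed from
those stored outputs (the mean of the two softmax vectors), so ensemble and
branch accuracies always refer to the same forward passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    BranchedClassifier,
    ModelConfig,
    build_cnn,
    build_rnn,
    ensemble_predict,
    stack_features,
    train_model,
)
from .standardize import StandardSample

METHODS = ("MCCV30", "SubMCCV50", "MCCV50")


@dataclass
class SplitPlan:
    """One realized train/test partition under a named protocol."""

    method: str
    train_indices: np.ndarray
    test_indices: np.ndarray
    repeat_id: int
    seed: int

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_indices, self.test_indices).size:
            raise ValueError("train and test indices overlap")


def _largest_remainder(quotas: np.ndarray, total: int, lo: np.ndarray, hi: np.ndarray):
    """Integer allocation: floor the quotas, then hand out the residual by
    largest fractional part, respecting per-participant [lo, hi] bounds."""
    base = np.floor(quotas).astype(int)
    base = np.clip(base, lo, hi)
    residual = total - base.sum()
    frac = quotas - np.floor(quotas)
    order = np.argsort(-frac, kind="stable")
    i = 0
    while residual != 0 and i < 10 * len(base):
        j = order[i % len(base)]
        if residual > 0 and base[j] < hi[j]:
            base[j] += 1
            residual -= 1
        elif residual < 0 and base[j] > lo[j]:
            base[j] -= 1
            residual += 1
        i += 1
    if residual != 0:
        raise ValueError("cannot satisfy split counts under per-class bounds")
    return base


def make_split(
    n_per_participant: "list[int] | np.ndarray",
    method: str,
    seed: int,
    repeat_id: int = 1,
) -> SplitPlan:
    """Draw one stratified MCCV split over participant-blocked global indices.

    Samples are indexed 0..N-1 in participant blocks (participant j owns
    ``n_per_participant[j]`` consecutive indices). Test totals are
    round(0.3*N) for MCCV30 and floor(N/2) for MCCV50, allocated across
    participants by largest remainder with at least one train and one test
    sample each; SubMCCV50 takes 2*floor(0.42*n_j) samples per participant
    and splits them evenly. Reproducible from ``seed``.
    """
    counts = np.asarray(n_per_participant, dtype=int)
    if np.any(counts < 2):
        raise ValueError("every participant needs at least 2 samples")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    rng = np.random.default_rng(seed)
    n_total = int(counts.sum())
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    lo = np.ones_like(counts)
    hi = counts - 1

    train_parts, test_parts = [], []
    if method in ("MCCV30", "MCCV50"):
        if method == "MCCV30":
            total_test = int(round(0.3 * n_total))
            quotas = 0.3 * counts
        else:
            total_test = n_total // 2
            quotas = 0.5 * counts
        test_counts = _largest_remainder(quotas, total_test, lo, hi)
        for j, c in enumerate(counts):
            perm = offsets[j] + rng.permutation(c)
            test_parts.append(perm[: test_counts[j]])
            train_parts.append(perm[test_counts[j] :])
    else:  # SubMCCV50
        for j, c in enumerate(counts):
            m = min(int(c), 2 * int(np.floor(0.42 * c)))
            m = max(m, 2)  # keep both halves non-empty
            half = m // 2
            perm = offsets[j] + rng.permutation(c)
            test_parts.append(perm[:half])
            train_parts.append(perm[half : 2 * half])
    return SplitPlan(
        method=method,
        train_indices=np.sort(np.concatenate(train_parts)),
        test_indices=np.sort(np.concatenate(test_parts)),
        repeat_id=repeat_id,
        seed=seed,
    )


def split_counts(samples: list[StandardSample]) -> tuple[list[str], np.ndarray]:
    """Participant order and per-participant sample counts, preserving the
    temporal/participant-block ordering of ``samples``."""
    order: list[str] = []
    counts: dict[str, int] = {}
    for s in samples:
        if s.participant_id not in counts:
            order.append(s.participant_id)
            counts[s.participant_id] = 0
        counts[s.participant_id] += 1
    return order, np.array([counts[p] for p in order])


def _sort_by_participant(samples: list[StandardSample]) -> list[StandardSample]:
    # stable: keeps temporal order within participant blocks
    return sorted(samples, key=lambda s: s.participant_id)


def accuracy(probs: np.ndarray, labels: np.ndarray) -> float:
    return float((probs.argmax(axis=1) == labels).mean())


def run_experiment(
    samples: list[StandardSample],
    cfg: ModelConfig,
    method: str = "MCCV30",
    repeats: int = 20,
    seed: int = 0,
) -> dict:
    """Repeat the split/train/test cycle and aggregate accuracies.

    Per repeat: a fresh split, independently trained CNN and RNN, test-set
    softmax outputs stored, and accuracies of the CNN, the RNN and their
    averaging ensemble. Returns per-repeat accuracies, their means, and the
    realized split sizes. Deterministic given ``seed``.
    """
    samples = _sort_by_participant(samples)
    _, counts = split_counts(samples)
    inputs, labels, classes = stack_features(samples, cfg.modalities)
    if len(classes) != cfg.n_classes:
        raise ValueError(
            f"config expects {cfg.n_classes} classes but data has {len(classes)}"
        )
    per_repeat: dict[str, list[float]] = {"cnn": [], "rnn": [], "ens": []}
    split_sizes = None
    master = np.random.default_rng(seed)
    for r in range(1, repeats + 1):
        split_seed, cnn_seed, rnn_seed = master.integers(0, 2**31 - 1, size=3)
        plan = make_split(counts, method, int(split_seed), repeat_id=r)
        split_sizes = (plan.train_indices.size, plan.test_indices.size)
        train = [samples[i] for i in plan.train_indices]
        test_inputs = {m: x[plan.test_indices] for m, x in inputs.items()}
        test_labels = labels[plan.test_indices]
        probs = {}
        for kind, build, s in (
            ("cnn", build_cnn, cnn_seed),
            ("rnn", build_rnn, rnn_seed),
        ):
            model_cfg = ModelConfig(**{**cfg.__dict__, "seed": int(s)})
            model = train_model(build(model_cfg), train, model_cfg)
            probs[kind] = model.predict_proba(test_inputs)
        probs["ens"] = ensemble_predict(probs["cnn"], probs["rnn"])
        for kind in ("cnn", "rnn", "ens"):
            per_repeat[kind].append(accuracy(probs[kind], test_labels))
    return {
        "method": method,
        "repeats": repeats,
        "n_samples": len(samples),
        "n_train": split_sizes[0],
        "n_test": split_sizes[1],
        "accuracy": per_repeat,
        "mean_accuracy": {k: float(np.mean(v)) for k, v in per_repeat.items()},
    }


def export_embedding(
    model: BranchedClassifier,
    samples: list[StandardSample],
    seed: int = 0,
    perplexity: float = 30.0,
) -> pd.DataFrame:
    """2-D t-SNE of the 256-unit FC-layer activations, one row per sample."""
    from sklearn.manifold import TSNE

    if model.classes_ is None:
        raise ValueError("model is not fitted")
    inputs, _, _ = stack_features(samples, model.cfg.modalities)
    feats = model.features_256(inputs)
    perplexity = min(perplexity, max(2.0, (len(samples) - 1) / 3))
    coords = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    ).fit_transform(feats)
    return pd.DataFrame(
        {
            "sample_id": np.arange(len(samples)),
            "participant": [s.participant_id for s in samples],
            "x": coords[:, 0],
            "y": coords[:, 1],
        }
    )
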