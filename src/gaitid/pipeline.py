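"""End-to-end composition: ingest/simulate -> segment -> standardize -> evaluate."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .evaluate import run_experiment
from .io_insole import InsoleRecording, load_dataset
from .models import ModelConfig
from .segmentation import (
    DEFAULT_MIN_SEP_S,
    DEFAULT_SIGMA_S,
    UnitStep,
    segment_recording,
)
from .standardize import StandardSample, build_standard_samples, group_k_steps
from .synthetic import simulate_cohort


def segment_dataset(
    recordings: list[InsoleRecording],
    sigma_s: float = DEFAULT_SIGMA_S,
    min_sep_s: float = DEFAULT_MIN_SEP_S,
) -> dict[str, dict[str, list[UnitStep]]]:
    """Segment every recording; maps participant -> foot -> steps in order."""
    return {
        rec.participant_id: segment_recording(rec, sigma_s, min_sep_s)
        for rec in recordings
    }


def samples_from_recordings(
    recordings: list[InsoleRecording],
    sigma_s: float = DEFAULT_SIGMA_S,
    min_sep_s: float = DEFAULT_MIN_SEP_S,
    d: int | None = None,
    k: int = 1,
) -> list[StandardSample]:
    """The full pre-processing chain, from raw recordings to model samples."""
    steps = segment_dataset(recordings, sigma_s, min_sep_s)
    return group_k_steps(build_standard_samples(steps, d=d), k)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Either ``manifest`` points at an on-disk dataset or ``n_participants``/
    ``duration_s``/``spur_rate`` describe a synthetic cohort to simulate.
    """

    manifest: str | None = None
    n_participants: int = 10
    duration_s: float = 180.0
    spur_rate: float = 0.02
    sigma_s: float = DEFAULT_SIGMA_S
    min_sep_s: float = DEFAULT_MIN_SEP_S
    d: int | None = None  # None: minimum observed step length
    k: int = 1
    modalities: tuple[str, ...] = ("p", "a", "r")
    method: str = "MCCV30"
    repeats: int = 1
    epochs: int = 50
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig, out_path: str | Path | None = None) -> dict:
    """Execute the whole pipeline and return (optionally write) the report."""
    if config.manifest is not None:
        manifest = Path(config.manifest)
        if not manifest.exists():
            raise FileNotFoundError(f"manifest not found: {manifest}")
        recordings = load_dataset(manifest)
    else:
        recordings = simulate_cohort(
            config.n_participants, config.duration_s, config.spur_rate, config.seed
        ).recordings
    samples = samples_from_recordings(
        recordings, config.sigma_s, config.min_sep_s, d=config.d, k=config.k
    )
    d_used = samples[0].d
    cfg = ModelConfig(
        modalities=tuple(config.modalities),
        d=d_used,
        k=config.k,
        n_classes=len({s.participant_id for s in samples}),
        seed=config.seed,
        epochs=config.epochs,
    )
    result = run_experiment(
        samples, cfg, method=config.method, repeats=config.repeats, seed=config.seed
    )
    report = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "d": d_used,
        "n_samples": len(samples),
        "result": result,
    }
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        out_path.write_text(json.dumps(report, indent=2))
    return report
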