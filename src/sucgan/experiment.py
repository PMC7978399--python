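"""Leave-one-out experiment orchestration.

Every subject is held out once; the networks are freshly He-initialized for
each split, trained on all remaining subjects' slices (with flip
augmentation), and the held-out subject's synthetic CT is evaluated against
its measured CT.  Split seeds derive from the base seed plus the split
index, and per-split failures are recorded in the manifest without aborting
the rest of the experiment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import (MetricsReport, SSIMParams, contour_metrics,
                         summarize_cohort)
from .nn import (DiscriminatorSpec, GeneratorSpec, PatchDiscriminator,
                 UNetGenerator, he_initialize, reference_discriminator_spec,
                 reference_sunet_spec, save_checkpoint)
from .training import TrainConfig, predict_volume, train
from .volumes import PairedCase

logger = logging.getLogger(__name__)

__all__ = ["LooSplit", "ExperimentManifest", "loo_splits", "run_loo_experiment"]


@dataclass(frozen=True)
class LooSplit:
    """One leave-one-out instance: who is held out and how much data trains.

    Slice counts are raw (pre-augmentation); flip augmentation doubles the
    training pool at fit time.
    """

    held_out_id: str
    train_ids: tuple
    n_train_slices: int
    n_test_slices: int

    def __post_init__(self) -> None:
        if self.held_out_id in self.train_ids:
            raise ValueError("held-out subject appears in the training ids")


@dataclass
class ExperimentManifest:
    """Paths and seeds of everything a leave-one-out run produced."""

    out_dir: str
    config: dict
    splits: List[dict] = field(default_factory=list)
    summary_path: Optional[str] = None

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(
            {"out_dir": self.out_dir, "config": self.config,
             "splits": self.splits, "summary_path": self.summary_path},
            indent=2, default=str))
        return path


def loo_splits(cases: Sequence[PairedCase]) -> List[LooSplit]:
    """All leave-one-out splits of a cohort, ordered by subject id."""
    if len(cases) < 2:
        raise ValueError("leave-one-out needs at least 2 subjects")
    ids = [c.subject_id for c in cases]
    if len(set(ids)) != len(ids):
        raise ValueError("subject ids must be unique")
    ordered = sorted(cases, key=lambda c: c.subject_id)
    total = sum(c.n_slices for c in ordered)
    splits = []
    for case in ordered:
        splits.append(LooSplit(
            held_out_id=case.subject_id,
            train_ids=tuple(c.subject_id for c in ordered
                            if c.subject_id != case.subject_id),
            n_train_slices=total - case.n_slices,
            n_test_slices=case.n_slices,
        ))
    return splits


def run_loo_experiment(cohort: Sequence[PairedCase], config: TrainConfig,
                       out_dir, generator_spec: Optional[GeneratorSpec] = None,
                       discriminator_spec: Optional[DiscriminatorSpec] = None,
                       ssim_params: SSIMParams = SSIMParams(),
                       save_checkpoints: bool = True) -> ExperimentManifest:
    """Train/evaluate every leave-one-out split and write cohort summaries."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gspec = generator_spec or reference_sunet_spec()
    dspec = discriminator_spec or reference_discriminator_spec()
    by_id = {c.subject_id: c for c in cohort}
    manifest = ExperimentManifest(out_dir=str(out), config={
        "train": asdict(config), "generator": asdict(gspec),
        "discriminator": asdict(dspec)})

    all_reports: List[MetricsReport] = []
    for i, split in enumerate(loo_splits(cohort)):
        split_seed = int(config.seed) + i
        entry: Dict[str, object] = {
            "held_out_id": split.held_out_id, "seed": split_seed,
            "n_train_slices": split.n_train_slices,
            "n_train_slices_augmented":
                split.n_train_slices * (2 if config.augment_flip else 1),
            "n_test_slices": split.n_test_slices,
        }
        try:
            gen = he_initialize(UNetGenerator(gspec), seed=split_seed)
            disc = he_initialize(PatchDiscriminator(dspec), seed=split_seed + 10_000)
            split_config = dataclasses.replace(config, seed=split_seed)
            train_cases = [by_id[sid] for sid in split.train_ids]
            gen, disc, history = train(gen, disc, train_cases, split_config)

            held = by_id[split.held_out_id]
            sct = predict_volume(gen, held.mr, split_config.ct_scale,
                                 dropout_seed=split_seed)
            reports = contour_metrics(held, sct, ssim_params)
            all_reports.extend(reports)

            report_path = out / f"metrics_{split.held_out_id}.csv"
            pd.DataFrame([vars(r) for r in reports]).to_csv(report_path, index=False)
            history_path = out / f"history_{split.held_out_id}.csv"
            history.to_dataframe().to_csv(history_path, index=False)
            entry["report"] = str(report_path)
            entry["history"] = str(history_path)
            if save_checkpoints:
                ckpt = save_checkpoint(out / f"ckpt_{split.held_out_id}.npz",
                                       gen, disc)
                entry["checkpoint"] = str(ckpt)
        except Exception as exc:  # isolate split failures
            logger.exception("split %s failed", split.held_out_id)
            entry["error"] = f"{type(exc).__name__}: {exc}"
        manifest.splits.append(entry)

    if all_reports:
        summary = summarize_cohort(all_reports)
        summary_path = out / "cohort_summary.csv"
        summary.to_csv(summary_path)
        manifest.summary_path = str(summary_path)
    manifest.to_json(out / "manifest.json")
    return manifest
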