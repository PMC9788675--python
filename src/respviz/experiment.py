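"""End-to-end experiment orchestration.

One call — :func:`run_experiment` — runs the full pipeline for every
requested (task, method) pair:

    synthesize corpus -> standardize audio -> render visualizations ->
    hold out test events -> oversample training images -> relabel for task
    -> 70/30 train/validation split -> train classifier -> evaluate.

Everything derives from one global seed; a rerun with the same config
reproduces the same manifests and metrics. When ``out_dir`` is given, the
run directory is self-describing: the config snapshot, per-stage manifests
and JSON metric reports are all written under it.
"""

from __future__ import annotations

import json
import logging
import os
import time
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import dataset as ds
from . import synthaudio, viz
from .metrics import confusion, evaluate
from .errors import ValidationError
from .model import ImageClassifier
from .preprocess import PreprocessConfig, standardize
from .types import ImageRecord

logger = logging.getLogger(__name__)

#: Corpus composition matching the study's class distribution
#: (training-pool sizes 19/11/89/17 plus an 8-per-class holdout).
DEFAULT_CLASS_COUNTS = {"wC": 27, "dC": 19, "whC": 97, "RB": 25}


@dataclass
class ExperimentConfig:
    """Every stage's knobs plus the global seed."""

    class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    tasks: tuple = ("C1", "C2", "C3")
    methods: tuple = viz.METHODS
    seed: int = 0
    n_test_per_class: int = 8
    balance: str = "oversample"  # or "undersample" / "none"
    noise_sigma: float = 5.0
    val_fraction: float = 0.30
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    stft: viz.StftConfig = field(default_factory=viz.StftConfig)
    mel: viz.MelConfig = field(default_factory=viz.MelConfig)
    log_axis: viz.LogAxisConfig = field(default_factory=viz.LogAxisConfig)
    cwt: viz.CwtConfig = field(default_factory=viz.CwtConfig)
    dynamic_range_db: float = 80.0
    colormap: str = "gray"
    backbone: str = "tiny"
    batch_size: int = 15
    max_epochs: int = 10
    base_learning_rate: float = 1.0e-4
    head_lr_factor: float = 20.0
    backbone_lr_multiplier: float = 1.0
    momentum: float = 0.9

    def validate(self) -> None:
        unknown = set(self.tasks) - set(ds.TASKS)
        if unknown:
            raise ValidationError(f"tasks: unknown {sorted(unknown)!r}")
        unknown = set(self.methods) - set(viz.METHODS)
        if unknown:
            raise ValidationError(f"methods: unknown {sorted(unknown)!r}")
        if self.balance not in ("oversample", "undersample", "none"):
            raise ValidationError(f"balance: unsupported {self.balance!r}")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tasks"] = list(self.tasks)
        d["methods"] = list(self.methods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key, sub in (("preprocess", PreprocessConfig), ("stft", viz.StftConfig),
                         ("mel", viz.MelConfig), ("log_axis", viz.LogAxisConfig),
                         ("cwt", viz.CwtConfig)):
            if key in d and isinstance(d[key], dict):
                sub_kwargs = dict(d[key])
                if key == "cwt" and "freq_limits" in sub_kwargs:
                    sub_kwargs["freq_limits"] = tuple(sub_kwargs["freq_limits"])
                d[key] = sub(**sub_kwargs)
        for key in ("tasks", "methods"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31 (crc32 is process-independent)."""
    return int(np.random.SeedSequence([seed, zlib.crc32(stage.encode()) % (2**31)])
               .generate_state(1)[0] % (2**31))


def build_image_records(events, cfg: ExperimentConfig) -> dict:
    """Standardize every event and render the requested methods.

    Returns ``{method: [ImageRecord, ...]}`` in event order.
    """
    records: dict = {m: [] for m in cfg.methods}
    t0 = time.time()
    for ev in events:
        std = standardize(ev, cfg.preprocess)
        images = viz.images_for_event(
            std, methods=cfg.methods, stft_cfg=cfg.stft, mel_cfg=cfg.mel,
            log_cfg=cfg.log_axis, cwt_cfg=cfg.cwt,
            dynamic_range_db=cfg.dynamic_range_db, colormap_tag=cfg.colormap,
        )
        for method, img in images.items():
            records[method].append(
                ImageRecord(image=img, event_id=ev.source_id, label=ev.label)
            )
    logger.info("rendered %d events x %d methods in %.1fs",
                len(events), len(cfg.methods), time.time() - t0)
    return records


def _prepare_task_sets(records, split, task, cfg: ExperimentConfig):
    """Balanced, task-labelled train/val/test image records for one method."""
    test_events = {eid for ids in split.test_ids.values() for eid in ids}
    pool = [r for r in records if r.event_id not in test_events]
    test = [r for r in records if r.event_id in test_events]

    if cfg.balance == "oversample":
        pool = ds.oversample_with_noise(pool, seed=_derive_seed(cfg.seed, "oversample"),
                                        noise_sigma=cfg.noise_sigma)
    elif cfg.balance == "undersample":
        pool = ds.undersample(pool, seed=_derive_seed(cfg.seed, "undersample"))

    pool = ds.relabel_for_task(pool, task)
    test = ds.relabel_for_task(test, task)
    train, val = ds.train_validation_split(
        pool, val_fraction=cfg.val_fraction, seed=_derive_seed(cfg.seed, "valsplit"),
    )
    ds.check_no_leakage(train, val, split)
    return train, val, test


def _records_to_arrays(records):
    X = np.stack([r.image.pixels for r in records])
    y = np.array([r.task_label for r in records])
    return X, y


def run_experiment(cfg: ExperimentConfig, out_dir: str | None = None) -> dict:
    """Run every (task, method) pair; returns ``{(task, method): MetricsReport}``."""
    cfg.validate()
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        cfg.to_yaml(os.path.join(out_dir, "config.yaml"))

    events, manifest = synthaudio.generate_corpus(
        cfg.class_counts, seed=_derive_seed(cfg.seed, "corpus")
    )
    if out_dir:
        manifest.to_csv(os.path.join(out_dir, "corpus_manifest.csv"), index=False)
    logger.info("synthesized %d events", len(events))

    try:
        split = ds.holdout_split(events, n_test_per_class=cfg.n_test_per_class,
                                 seed=_derive_seed(cfg.seed, "holdout"))
    except Exception as exc:
        raise RuntimeError(f"stage (holdout) failed: {exc}") from exc
    records_by_method = build_image_records(events, cfg)

    reports: dict = {}
    for task_id in cfg.tasks:
        task = ds.TASKS[task_id]
        for method in cfg.methods:
            t0 = time.time()
            try:
                train, val, test = _prepare_task_sets(
                    records_by_method[method], split, task, cfg
                )
                X_tr, y_tr = _records_to_arrays(train)
                X_va, y_va = _records_to_arrays(val)
                X_te, y_te = _records_to_arrays(test)
                clf = ImageClassifier(
                    backbone=cfg.backbone, batch_size=cfg.batch_size,
                    max_epochs=cfg.max_epochs,
                    base_learning_rate=cfg.base_learning_rate,
                    head_lr_factor=cfg.head_lr_factor,
                    backbone_lr_multiplier=cfg.backbone_lr_multiplier,
                    momentum=cfg.momentum,
                    random_state=_derive_seed(cfg.seed, f"train-{task_id}-{method}"),
                )
                clf.fit(X_tr, y_tr, X_val=X_va, y_val=y_va)
                y_pred = clf.predict(X_te)
                report = evaluate(y_te, y_pred, class_order=task.classes)
            except Exception as exc:
                raise RuntimeError(
                    f"stage (task={task_id}, method={method}) failed: {exc}"
                ) from exc
            reports[(task_id, method)] = report
            logger.info("(%s, %s): acc=%.3f kappa=%s  [%.1fs]",
                        task_id, method, report.accuracy,
                        report.cohens_kappa, time.time() - t0)
            if out_dir:
                name = f"report_{task_id}_{method}"
                with open(os.path.join(out_dir, name + ".json"), "w") as fh:
                    json.dump(report.to_dict(), fh, indent=2)
                pd.DataFrame(
                    confusion(y_te, y_pred, task.classes).matrix,
                    index=task.classes, columns=task.classes,
                ).to_csv(os.path.join(out_dir, name + "_confusion.csv"))
    return reports
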