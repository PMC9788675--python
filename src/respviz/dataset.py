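"""Task-labelled, class-balanced train/validation/test set construction.

The corpus is heavily imbalanced (whooping cough dominates), so the
builder follows a fixed order designed to keep the test set honest:

1. **hold out** a fixed number of events per class (default 8, roughly 10%
   of the largest class) *before* any augmentation — test images can never
   be duplicates, and no image derived from a test event reaches training;
2. **oversample** the remaining training-pool images per original class up
   to the largest class's count by duplicating uniformly chosen originals
   and overlaying seeded Gaussian pixel noise on every duplicate (so no
   duplicate is an exact copy);
3. **relabel** for the requested task — C1 keeps the four classes, C2 keeps
   wet vs dry cough only, C3 merges the three cough classes against
   restricted breathing;
4. split the (augmented) training data 70/30 into training and validation,
   stratified by task label.

Undersampling to the smallest class is available as an alternative
balancing strategy for comparison; oversampling is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .errors import ValidationError
from .types import CLASS_LABELS, ImageRecord, RenderedImage

EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class TaskDefinition:
    """A classification task: a label map over the four source classes."""

    task_id: str
    label_map: dict

    def target_label(self, source_label: str) -> str:
        if source_label not in self.label_map:
            raise ValidationError(f"label: unknown class {source_label!r}")
        return self.label_map[source_label]

    @property
    def classes(self) -> tuple:
        seen = []
        for v in self.label_map.values():
            if v != EXCLUDED and v not in seen:
                seen.append(v)
        return tuple(seen)


#: The three evaluated tasks.
TASKS = {
    "C1": TaskDefinition("C1", {c: c for c in CLASS_LABELS}),
    "C2": TaskDefinition("C2", {"wC": "wC", "dC": "dC",
                                "whC": EXCLUDED, "RB": EXCLUDED}),
    "C3": TaskDefinition("C3", {"wC": "cough", "dC": "cough",
                                "whC": "cough", "RB": "RB"}),
}


@dataclass
class DatasetSplit:
    """Event-level assignment to the test set vs the training pool."""

    test_ids: dict  # class -> tuple of event ids
    train_ids: dict  # class -> tuple of event ids
    n_test_per_class: int
    seed: int

    def split_of(self, event_id: str) -> str:
        for ids in self.test_ids.values():
            if event_id in ids:
                return "test"
        return "train"


def holdout_split(events, n_test_per_class: int = 8, seed: int = 0) -> DatasetSplit:
    """Set aside ``n_test_per_class`` events per class, before augmentation.

    ``events`` is any sequence of objects with a ``label`` and an event
    identifier (``source_id`` for audio events, ``event_id`` for image
    records). Sampling is uniform without replacement, seeded; an event id
    appearing multiple times (several images of one event) is assigned once.
    """
    if n_test_per_class < 0:
        raise ValidationError("n_test_per_class: must be >= 0")
    by_class: dict = {}
    seen = set()
    for ev in events:
        eid = getattr(ev, "source_id", None) or ev.event_id
        if eid not in seen:
            seen.add(eid)
            by_class.setdefault(ev.label, []).append(eid)
    rng = np.random.default_rng(seed)
    test_ids, train_ids = {}, {}
    for label in sorted(by_class):
        ids = by_class[label]
        if n_test_per_class > 0 and len(ids) < n_test_per_class + 1:
            raise ValidationError(
                f"class {label!r}: only {len(ids)} events, need at least "
                f"{n_test_per_class + 1} for an {n_test_per_class}-event holdout"
            )
        chosen = rng.choice(len(ids), size=n_test_per_class, replace=False)
        mask = np.zeros(len(ids), dtype=bool)
        mask[chosen] = True
        test_ids[label] = tuple(ids[i] for i in np.flatnonzero(mask))
        train_ids[label] = tuple(ids[i] for i in np.flatnonzero(~mask))
    return DatasetSplit(test_ids=test_ids, train_ids=train_ids,
                        n_test_per_class=n_test_per_class, seed=seed)


def _with_noise(pixels: np.ndarray, rng: np.random.Generator, sigma: float) -> np.ndarray:
    noisy = np.clip(
        np.round(pixels.astype(np.float64) + rng.normal(0.0, sigma, pixels.shape)),
        0, 255,
    ).astype(np.uint8)
    return noisy


def oversample_with_noise(records, seed: int = 0, noise_sigma: float = 5.0,
                          classes=None) -> list:
    """Balance classes up to the largest class by noisy image duplication.

    Each added image is a uniformly chosen original with additive Gaussian
    pixel noise (sigma on the 8-bit scale) clipped to [0, 255], flagged
    ``duplicated`` and carrying its source's event id. Originals pass
    through unmodified. Already-balanced input is returned as-is. When
    ``classes`` is given, every listed class must contribute at least one
    image.
    """
    by_class: dict = {c: [] for c in (classes or ())}
    for rec in records:
        by_class.setdefault(rec.label, []).append(rec)
    if not by_class:
        return []
    for label, recs in by_class.items():
        if not recs:
            raise ValidationError(f"class {label!r}: empty, cannot oversample")
    target = max(len(r) for r in by_class.values())
    rng = np.random.default_rng(seed)
    out = list(records)
    for label in sorted(by_class):
        originals = by_class[label]
        for _ in range(target - len(originals)):
            src = originals[int(rng.integers(len(originals)))]
            noisy = _with_noise(src.image.pixels, rng, noise_sigma)
            while np.array_equal(noisy, src.image.pixels):  # σ=0-like fluke guard
                noisy = _with_noise(src.image.pixels, rng, max(noise_sigma, 1.0))
            out.append(ImageRecord(
                image=RenderedImage(pixels=noisy, method_tag=src.image.method_tag,
                                    provenance=src.image.provenance),
                event_id=src.event_id, label=src.label, duplicated=True,
            ))
    return out


def undersample(records, seed: int = 0) -> list:
    """Alternative balancing: subsample every class to the smallest count."""
    by_class: dict = {}
    for rec in records:
        by_class.setdefault(rec.label, []).append(rec)
    if not by_class:
        return []
    target = min(len(r) for r in by_class.values())
    rng = np.random.default_rng(seed)
    out = []
    for label in sorted(by_class):
        recs = by_class[label]
        keep = rng.choice(len(recs), size=target, replace=False)
        out.extend(recs[i] for i in sorted(keep))
    return out


def relabel_for_task(records, task: TaskDefinition) -> list:
    """Map class labels onto task labels; EXCLUDED records are dropped.

    Idempotent: records already carrying a task label of this task pass
    through unchanged.
    """
    out = []
    task_classes = set(task.classes)
    for rec in records:
        if rec.task_label is not None and rec.task_label in task_classes:
            out.append(rec)
            continue
        target = task.target_label(rec.label)
        if target == EXCLUDED:
            continue
        out.append(ImageRecord(image=rec.image, event_id=rec.event_id,
                               label=rec.label, task_label=target,
                               duplicated=rec.duplicated, split=rec.split))
    return out


def train_validation_split(records, val_fraction: float = 0.30, seed: int = 0):
    """Stratified split of the augmented training images into train/val."""
    if not 0 < val_fraction < 1:
        raise ValidationError("val_fraction: must lie in (0, 1)")
    labels = [rec.task_label or rec.label for rec in records]
    idx_train, idx_val = train_test_split(
        np.arange(len(records)), test_size=val_fraction,
        random_state=seed % (2**32), stratify=labels,
    )
    train = [records[i] for i in sorted(idx_train)]
    val = [records[i] for i in sorted(idx_val)]
    for rec in train:
        rec.split = "train"
    for rec in val:
        rec.split = "validation"
    return train, val


def check_no_leakage(train_records, val_records, split: DatasetSplit) -> None:
    """Assert no image derived from a held-out event reaches train/val."""
    test_events = {eid for ids in split.test_ids.values() for eid in ids}
    for name, records in (("train", train_records), ("validation", val_records)):
        leaked = {r.event_id for r in records} & test_events
        if leaked:
            raise ValidationError(
                f"{name}: images derived from held-out events {sorted(leaked)!r}"
            )
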