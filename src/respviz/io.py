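"""PNG + CSV-manifest persistence for rendered images."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from PIL import Image

from .types import ImageRecord, RenderedImage


def save_images(records: list, out_dir: str, manifest_name: str = "images.csv") -> pd.DataFrame:
    """Write each record as PNG plus a sidecar CSV manifest."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        dup = "-dup%d" % i if rec.duplicated else ""
        fname = f"{rec.event_id}_{rec.image.method_tag}{dup}.png"
        path = os.path.join(out_dir, fname)
        Image.fromarray(rec.image.pixels, mode="RGB").save(path)
        rows.append({
            "path": path, "event_id": rec.event_id, "label": rec.label,
            "method": rec.image.method_tag, "task_label": rec.task_label or "",
            "split": rec.split or "", "duplicated": rec.duplicated,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, manifest_name), index=False)
    return manifest


def load_images(manifest_path: str) -> list:
    """Read image records back from a manifest written by :func:`save_images`."""
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    records = []
    for _, row in manifest.iterrows():
        pixels = np.asarray(Image.open(row["path"]).convert("RGB"), dtype=np.uint8)
        records.append(ImageRecord(
            image=RenderedImage(pixels=pixels, method_tag=row["method"],
                                provenance=str(row["event_id"])),
            event_id=str(row["event_id"]), label=row["label"],
            task_label=row["task_label"] or None,
            duplicated=bool(row["duplicated"]),
            split=row["split"] or None,
        ))
    return records
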