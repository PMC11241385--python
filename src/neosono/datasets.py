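"""Labelled composite datasets: in-memory container and directory layout.

On disk a dataset is one folder per class (``Normal/``, ``Moderate/``,
``Intensive/``) of composite PNGs plus a ``manifest.csv`` with one row per
sample (sample id, label, and any provenance columns such as the realized
delta-E).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .density import CLASS_NAMES

__all__ = ["LabeledDataset"]


@dataclass
class LabeledDataset:
    """Composite images ``X`` (n, H, W, 3) uint8 with labels and manifest."""

    X: np.ndarray
    y: np.ndarray
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y) or len(self.X) != len(self.manifest):
            raise ValueError("X, y and manifest must have equal length")

    def __len__(self) -> int:
        return len(self.y)

    def class_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def to_directory(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for cls in np.unique(self.y):
            (path / str(cls)).mkdir(exist_ok=True)
        for i, sid in enumerate(self.manifest["sample_id"]):
            cls = str(self.y[i])
            iio.imwrite(path / cls / f"{sid}.png", self.X[i])
        self.manifest.to_csv(path / "manifest.csv", index=False)

    @classmethod
    def from_directory(cls, path: str | Path) -> "LabeledDataset":
        path = Path(path)
        manifest = pd.read_csv(path / "manifest.csv")
        images, labels = [], []
        for _, row in manifest.iterrows():
            label = str(row["label"])
            px = iio.imread(path / label / f"{row['sample_id']}.png")
            if px.ndim == 2:
                px = np.repeat(px[:, :, None], 3, axis=2)
            images.append(px)
            labels.append(label)
        return cls(
            X=np.stack(images),
            y=np.asarray(labels, dtype=object),
            manifest=manifest,
        )
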