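"""In-memory containers shared by the balancing, training and evaluation stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import RANKS


@dataclass
class ColonyDataset:
    """Per-dish images with fully imputed six-rank labels and a split.

    ``images`` is ``(n, side, side, 3)`` uint8; ``labels`` a DataFrame with
    the six rank columns (no missing values — impute first); ``partition``
    an array of ``'train'``/``'test'`` tags.  ``images_hires`` optionally
    holds a higher-resolution rendition of the same dishes for crop-based
    augmentation; ``fold`` optionally holds CV fold indices.
    """

    images: np.ndarray
    labels: pd.DataFrame
    partition: np.ndarray
    images_hires: np.ndarray | None = None
    fold: np.ndarray | None = None
    records: list | None = None

    def __post_init__(self):
        n = len(self.images)
        if len(self.labels) != n or len(self.partition) != n:
            raise ValueError("images, labels and partition lengths differ")
        for r in RANKS:
            if r not in self.labels.columns:
                raise ValueError(f"labels lack rank column {r!r}")

    @property
    def n(self) -> int:
        return len(self.images)

    @property
    def side(self) -> int:
        return self.images.shape[1]

    def train_indices(self) -> np.ndarray:
        return np.flatnonzero(self.partition == "train")

    def test_indices(self) -> np.ndarray:
        return np.flatnonzero(self.partition == "test")

    def labels_at(self, rank: str, idx=None) -> np.ndarray:
        col = self.labels[rank].to_numpy()
        return col if idx is None else col[idx]

    def subset(self, idx) -> "ColonyDataset":
        idx = np.asarray(idx)
        return ColonyDataset(
            images=self.images[idx],
            labels=self.labels.iloc[idx].reset_index(drop=True),
            partition=self.partition[idx],
            images_hires=None if self.images_hires is None else self.images_hires[idx],
            fold=None if self.fold is None else self.fold[idx],
            records=None if self.records is None else [self.records[i] for i in idx],
        )

    def with_partition(self, partition: np.ndarray) -> "ColonyDataset":
        out = ColonyDataset(
            images=self.images,
            labels=self.labels,
            partition=np.asarray(partition),
            images_hires=self.images_hires,
            fold=self.fold,
            records=self.records,
        )
        return out


@dataclass
class DatasetVariant:
    """One of the three imbalance treatments of a dataset.

    ``provenance`` holds one entry per synthetic (oversampled) image:
    donor row index, donor isolate id and the transform applied, so every
    synthetic image is auditable and donor/copy co-partitioning can be
    checked.
    """

    name: str  # 'original' | 'naive' | 'augmented'
    dataset: ColonyDataset
    balanced_rank: str | None = None
    provenance: list[dict] = field(default_factory=list)
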