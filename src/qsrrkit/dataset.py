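"""Joined descriptor/response datasets and the training/test split.

The calibration corpus is split randomly 70:30, but the compounds with the
global minimum and maximum retention index are always forced into the
training set, so that every test-set prediction is an interpolation of the
calibrated retention range — the same philosophy as the leverage
applicability domain.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix

__all__ = ["RIDataset", "split_train_test", "round_half_away"]

TRAIN, TEST, EXTERNAL = "training", "test", "external"


@dataclass
class RIDataset:
    """Compounds × descriptors with retention indices and split labels."""

    descriptors: DescriptorMatrix
    ri: pd.Series
    split: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.descriptors.values.index
        self.ri = pd.Series(np.asarray(self.ri, dtype=float), index=idx)
        if self.split is None:
            self.split = pd.Series("", index=idx, dtype=object)
        else:
            self.split = pd.Series(list(self.split), index=idx, dtype=object)
            bad = set(self.split.unique()) - {TRAIN, TEST, EXTERNAL, ""}
            if bad:
                raise ValueError(f"unknown split labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.ri)

    @property
    def compound_ids(self) -> list[str]:
        return self.descriptors.compound_ids

    def rows(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) for one split label."""
        mask = (self.split == label).to_numpy()
        X = self.descriptors.values.to_numpy()[mask]
        y = self.ri.to_numpy()[mask]
        return X, y

    def to_csv(self, path: str | Path) -> None:
        df = self.descriptors.values.copy()
        df.insert(0, "ri", self.ri)
        df.insert(1, "split", self.split)
        df.index.name = "compound_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RIDataset":
        df = pd.read_csv(path, index_col="compound_id")
        ri = df.pop("ri")
        split = df.pop("split").fillna("") if "split" in df else None
        return cls(DescriptorMatrix(df), ri, split)


def round_half_away(x: float) -> int:
    """Round half away from zero (so 185.5 → 186)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -round_half_away(-x)


def split_train_test(ds: RIDataset, train_fraction: float = 0.7,
                     seed: int = 0,
                     sidecar: str | Path | None = None) -> RIDataset:
    """Random training/test split with the extreme-RI pinning constraint.

    The training-set size is ``round_half_away(train_fraction * n)``; the
    compounds carrying the global minimum and maximum RI are assigned to the
    training set before the remaining compounds are shuffled.  Compounds
    already labelled ``external`` are left untouched and excluded from the
    split arithmetic.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    pool = [i for i, lab in zip(ds.ri.index, ds.split) if lab != EXTERNAL]
    n = len(pool)
    if n < 3:
        raise ValueError(f"need at least 3 non-external compounds, got {n}")
    n_train = round_half_away(train_fraction * n)
    ri = ds.ri.loc[pool]
    pinned = {ri.idxmin(), ri.idxmax()}
    rest = [i for i in pool if i not in pinned]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rest))
    n_more = n_train - len(pinned)
    train_ids = set(pinned) | {rest[k] for k in order[:n_more]}
    labels = ds.split.copy()
    for i in pool:
        labels.loc[i] = TRAIN if i in train_ids else TEST
    out = RIDataset(ds.descriptors, ds.ri, labels)
    if sidecar is not None:
        Path(sidecar).write_text(json.dumps(
            {"seed": seed, "train_fraction": train_fraction,
             "n_train": n_train, "n_test": n - n_train}, indent=2))
    return out
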