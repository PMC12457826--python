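"""Integer-coded ordinal dataset shared by the learning and effects stages."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OrdinalDataset"]


@dataclass
class OrdinalDataset:
    """A table of ordinal variables coded 0 .. L_k - 1.

    ``level_labels`` keeps the original labels tau(k, l) for reporting when a
    column arrived with non-contiguous codes and was compressed.
    """

    data: pd.DataFrame
    n_levels: dict[str, int]
    level_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in self.data.columns:
            vals = self.data[col].to_numpy()
            if not np.issubdtype(vals.dtype, np.integer):
                raise ValueError(f"column {col!r} is not integer-coded")
            if vals.min() < 0 or vals.max() >= self.n_levels[col]:
                raise ValueError(f"column {col!r} has codes outside its level range")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n(self) -> int:
        return len(self.data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OrdinalDataset":
        """Build from an integer table, compressing unoccupied levels.

        Each column is recoded to consecutive integers starting at 0; a gap
        (an unobserved level between observed ones) is collapsed with a
        warning since its latent threshold interval would be empty.
        """
        out = {}
        n_levels = {}
        labels = {}
        for col in frame.columns:
            vals = np.asarray(frame[col])
            if not np.issubdtype(vals.dtype, np.integer):
                as_int = vals.astype(int)
                if not np.array_equal(as_int, vals):
                    raise ValueError(f"column {col!r} is not integer-valued")
                vals = as_int
            uniq = np.unique(vals)
            if len(uniq) < 2:
                raise ValueError(
                    f"column {col!r} has a single occupied level; "
                    "it carries no ordinal information"
                )
            expected = np.arange(vals.min(), vals.max() + 1)
            if len(uniq) < len(expected) or uniq[0] != 0:
                if len(uniq) < len(expected):
                    warnings.warn(
                        f"column {col!r}: collapsing {len(expected) - len(uniq)} "
                        "unoccupied level(s)",
                        stacklevel=2,
                    )
                recode = {v: i for i, v in enumerate(uniq)}
                vals = np.vectorize(recode.get)(vals)
            out[col] = vals
            n_levels[col] = len(uniq)
            labels[col] = uniq
        return cls(pd.DataFrame(out, index=frame.index), n_levels, labels)

    def counts(self, col: str) -> np.ndarray:
        return np.bincount(self.data[col].to_numpy(), minlength=self.n_levels[col])

    def as_matrix(self) -> np.ndarray:
        return self.data.to_numpy()

    def resample(self, rng: np.random.Generator) -> "OrdinalDataset":
        """Bootstrap resample of records (rows with replacement)."""
        idx = rng.integers(0, self.n, size=self.n)
        frame = self.data.iloc[idx].reset_index(drop=True)
        # occupancy can change under resampling; recompress defensively
        return OrdinalDataset.from_frame(frame)
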