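"""Labeled 3D marker sets for grid-phantom distortion analysis.

A marker is a beam-intersection point of the grid phantom, identified by an
integer lattice index (i, j, k) and a world-space position in mm.  Detected
sets additionally carry the normalized cross-correlation score of the
template match; reference (theoretical) sets do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class MarkerSet:
    """A set of labeled grid markers.

    Attributes
    ----------
    ids : (n,) array of int
        Unique marker labels.
    grid_index : (n, 3) array of int
        Lattice index of each marker along the three grid axes.
    pos_mm : (n, 3) array of float
        World coordinates in mm.
    score : (n,) array of float or None
        NCC detection score in [-1, 1]; NaN for markers that were searched
        for but not found; None for reference sets.
    """

    ids: np.ndarray
    grid_index: np.ndarray
    pos_mm: np.ndarray
    score: np.ndarray | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=int)
        self.grid_index = np.asarray(self.grid_index, dtype=int)
        self.pos_mm = np.asarray(self.pos_mm, dtype=float)
        if self.score is not None:
            self.score = np.asarray(self.score, dtype=float)
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("marker ids must be unique")
        if self.grid_index.shape != (len(self.ids), 3):
            raise ValueError("grid_index must be (n, 3)")
        if self.pos_mm.shape != (len(self.ids), 3):
            raise ValueError("pos_mm must be (n, 3)")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def found(self) -> np.ndarray:
        """Boolean mask of markers with finite positions (detected)."""
        return np.isfinite(self.pos_mm).all(axis=1)

    def select(self, mask) -> "MarkerSet":
        mask = np.asarray(mask)
        return MarkerSet(
            ids=self.ids[mask],
            grid_index=self.grid_index[mask],
            pos_mm=self.pos_mm[mask],
            score=None if self.score is None else self.score[mask],
        )

    def central_block(self, size: int = 3) -> np.ndarray:
        """Boolean mask selecting the central ``size**3`` block by grid index.

        Requires an odd number of lattice lines per axis so the block is
        unambiguous; raises otherwise.
        """
        if size % 2 == 0:
            raise ValueError("central block size must be odd")
        half = size // 2
        sel = np.ones(len(self), dtype=bool)
        for ax in range(3):
            lines = np.unique(self.grid_index[:, ax])
            if len(lines) % 2 == 0:
                raise ValueError(
                    "even number of grid lines along axis "
                    f"{ax}; central selection is ambiguous — pass an explicit mask"
                )
            mid = lines[len(lines) // 2]
            sel &= np.abs(self.grid_index[:, ax] - mid) <= half
        return sel

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "i": self.grid_index[:, 0],
                "j": self.grid_index[:, 1],
                "k": self.grid_index[:, 2],
                "x_mm": self.pos_mm[:, 0],
                "y_mm": self.pos_mm[:, 1],
                "z_mm": self.pos_mm[:, 2],
            }
        )
        if self.score is not None:
            df["score"] = self.score
        return df

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerSet":
        return cls(
            ids=df["id"].to_numpy(),
            grid_index=df[["i", "j", "k"]].to_numpy(),
            pos_mm=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
            score=df["score"].to_numpy() if "score" in df else None,
        )

    @classmethod
    def load_tsv(cls, path) -> "MarkerSet":
        return cls.from_frame(pd.read_csv(Path(path), sep="\t"))


def match_by_index(a: MarkerSet, b: MarkerSet) -> tuple[np.ndarray, np.ndarray]:
    """Indices into a and b of markers sharing a grid index, in a's order."""
    key_b = {tuple(gi): i for i, gi in enumerate(b.grid_index)}
    ia, ib = [], []
    for i, gi in enumerate(a.grid_index):
        j = key_b.get(tuple(gi))
        if j is not None:
            ia.append(i)
            ib.append(j)
    return np.asarray(ia, dtype=int), np.asarray(ib, dtype=int)
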