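"""Fixed-length per-image feature vectors grouped into named blocks.

A :class:`FeatureBlock` is the unit every extractor produces and every fusion /
selection / classification stage consumes: a dense ``(n_images, length)`` float
matrix with one named column per feature and, for fused blocks, a provenance
label recording which source block each column came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError

__all__ = ["FeatureBlock"]


@dataclass
class FeatureBlock:
    """A named, fixed-length numeric feature vector per image.

    Parameters
    ----------
    name:
        Block identity, conventionally one of ``"texton"``, ``"deep"``,
        ``"fused"`` (any string is accepted).
    values:
        Array of shape ``(n_images, length)``; coerced to ``float64``.
    columns:
        One name per feature column.
    provenance:
        Originating block per column.  Defaults to ``name`` for every column;
        fused blocks carry their sources' names instead.
    """

    name: str
    values: np.ndarray
    columns: list[str]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise AlignmentError(
                f"block {self.name!r}: values must be 2-D (n_images, length), "
                f"got shape {self.values.shape}"
            )
        self.columns = list(self.columns)
        if len(self.columns) != self.values.shape[1]:
            raise AlignmentError(
                f"block {self.name!r}: {len(self.columns)} column names for "
                f"{self.values.shape[1]} columns"
            )
        if not self.provenance:
            self.provenance = [self.name] * self.values.shape[1]
        elif len(self.provenance) != self.values.shape[1]:
            raise AlignmentError(
                f"block {self.name!r}: provenance length mismatch"
            )

    @property
    def n_images(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]

    def subset(self, indices, name: str | None = None) -> "FeatureBlock":
        """Column subset preserving names and provenance (row count unchanged)."""
        idx = np.asarray(indices, dtype=int)
        return FeatureBlock(
            name=name or self.name,
            values=self.values[:, idx],
            columns=[self.columns[i] for i in idx],
            provenance=[self.provenance[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)

    @classmethod
    def from_frame(cls, name: str, frame: pd.DataFrame) -> "FeatureBlock":
        return cls(name=name, values=frame.to_numpy(dtype=np.float64),
                   columns=list(map(str, frame.columns)))
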