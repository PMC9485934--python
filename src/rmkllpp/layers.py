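"""Core in-memory containers for omics matrices and feature annotation.

An :class:`OmicsLayer` is one omics data matrix oriented features x samples,
the orientation in which expression and methylation matrices are
distributed. Missing entries are encoded as NaN; the missingness mask is
derived, never stored separately, so it cannot drift out of sync.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["OmicsLayer", "AnnotationTable"]


@dataclass
class OmicsLayer:
    """One omics data matrix (features x samples) with identifiers.

    Parameters
    ----------
    name : str
        Layer label, e.g. ``"mrna"``, ``"mirna"``, ``"methylation"``.
    values : ndarray of shape (n_features, n_samples)
        Numeric matrix; NaN marks a missing entry.
    feature_ids : ndarray of str
    sample_ids : ndarray of str
    """

    name: str
    values: np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError(f"layer {self.name!r}: values must be 2-D")
        nf, ns = self.values.shape
        if nf != len(self.feature_ids):
            raise ValueError(
                f"layer {self.name!r}: {nf} rows but {len(self.feature_ids)} feature ids"
            )
        if ns != len(self.sample_ids):
            raise ValueError(
                f"layer {self.name!r}: {ns} columns but {len(self.sample_ids)} sample ids"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError(f"layer {self.name!r}: duplicate feature ids")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where an entry is missing."""
        return np.isnan(self.values)

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def select_features(self, keep: np.ndarray) -> "OmicsLayer":
        """Row-subset the layer, preserving order. `keep` is a boolean or index array."""
        return replace(
            self,
            values=self.values[keep].copy(),
            feature_ids=self.feature_ids[keep].copy(),
        )

    def select_samples(self, keep: np.ndarray) -> "OmicsLayer":
        return replace(
            self,
            values=self.values[:, keep].copy(),
            sample_ids=self.sample_ids[keep].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids.astype(str), columns=self.sample_ids.astype(str)
        )

    @classmethod
    def from_frame(cls, name: str, df: pd.DataFrame) -> "OmicsLayer":
        return cls(
            name=name,
            values=df.to_numpy(dtype=float),
            feature_ids=df.index.to_numpy(dtype=object),
            sample_ids=df.columns.to_numpy(dtype=object),
        )


@dataclass
class AnnotationTable:
    """BED-like CpG/feature annotation: chromosome, 0-based position,
    feature id and signed distance to the nearest transcription start site."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("chrom", "position", "feature_id", "distance_to_tss")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        if self.table["feature_id"].duplicated().any():
            raise ValueError("annotation table has duplicate feature ids")

    def __len__(self) -> int:
        return len(self.table)
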