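"""TSV/BED file I/O and run configuration.

Matrix dialect: tab-separated, header row of sample ids, first column
feature ids, numeric cells with ``NA`` (or an empty cell) marking missing.
Annotation dialect: BED-like TSV with 0-based positions and columns
chrom, position, feature_id, distance_to_tss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .layers import AnnotationTable, OmicsLayer

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_clinical_tsv",
    "RunConfig",
]

_NA_VALUES = ["NA", ""]


def read_matrix_tsv(path, name: str | None = None) -> OmicsLayer:
    """Parse a features x samples TSV matrix into an :class:`OmicsLayer`.

    Rejects duplicate feature ids, ragged rows and non-numeric cells with
    the offending line/id in the message.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=_NA_VALUES, keep_default_na=False
        )
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed TSV ({err})") from err
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        line = int(np.flatnonzero(df.index == dup)[-1]) + 2  # +1 header, +1 1-based
        raise ValueError(f"{path}: duplicate feature id {dup!r} at line {line}")
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna() | c.isna()).all()]
    try:
        values = df.apply(pd.to_numeric).to_numpy(dtype=float)
    except (ValueError, TypeError) as err:
        raise ValueError(f"{path}: non-numeric cell (columns {list(bad[:3])}): {err}") from err
    return OmicsLayer(
        name=name or path.stem,
        values=values,
        feature_ids=df.index.to_numpy(dtype=object),
        sample_ids=df.columns.to_numpy(dtype=object),
    )


def write_matrix_tsv(layer: OmicsLayer, path) -> None:
    df = layer.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_annotation_tsv(path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t")
    return AnnotationTable(df)


def write_annotation_tsv(ann: AnnotationTable, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_clinical_tsv(path) -> pd.DataFrame:
    """Clinical table: sample_id, time, event and optional age/gender/stage."""
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: clinical table missing columns {sorted(missing)}")
    df["time"] = pd.to_numeric(df["time"])
    df["event"] = pd.to_numeric(df["event"]).astype(int)
    if (df["time"] <= 0).any():
        raise ValueError(f"{path}: survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event indicator must be 0/1")
    return df


@dataclass
class RunConfig:
    """Flat configuration for an end-to-end run (YAML key-value file)."""

    layers: dict = field(default_factory=dict)  # name -> matrix TSV path
    clinical: str = ""
    annotation: str | None = None  # methylation CpG annotation, optional
    methylation_layers: tuple = ()  # layer names the annotation filter applies to
    log_transform_layers: tuple = ()  # layer names to log2(x+1) transform
    max_missing_rate: float = 0.30
    k_impute: int = 10
    promoter_window_bp: int = 2000
    excluded_chroms: tuple = ("chrX", "chrY")
    bandwidth_factors: tuple = (0.5, 1.0, 2.0)
    p_dim: int = 5
    k_neighbors: int = 9
    max_iter: int = 30
    tol: float = 1e-6
    ridge: float = 1e-3
    init: str = "A_first"
    k_range: tuple = (2, 10)
    n_init: int = 50
    merge_alpha: float = 0.05
    merge: bool = True
    seed: int = 0
    out_dir: str = "rmkllpp_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.layers:
            raise ValueError("config: at least one layer path required")
        for name, p in self.layers.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"config: layer {name!r} file not found: {p}")
        if self.clinical and not Path(self.clinical).exists():
            raise FileNotFoundError(f"config: clinical file not found: {self.clinical}")
        if self.annotation and not Path(self.annotation).exists():
            raise FileNotFoundError(f"config: annotation file not found: {self.annotation}")
        if not 0 <= self.max_missing_rate < 1:
            raise ValueError("config: max_missing_rate must be in [0, 1)")
        if self.p_dim < 1 or self.k_neighbors < 1:
            raise ValueError("config: p_dim and k_neighbors must be positive")

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out
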