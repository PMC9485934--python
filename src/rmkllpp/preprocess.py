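"""Per-layer preprocessing: missingness filter, KNN imputation, log2(x+1),
and promoter/sex-chromosome annotation filtering for methylation arrays.

Conventions (logged once here so they are auditable):

* "more than 30% missing" is read strictly: a feature is dropped when its
  missing fraction is > ``max_missing_rate``, so exactly 30% survives.
* "within 2 kb of a transcription start site" is read inclusively:
  |distance_to_tss| <= ``promoter_window_bp``.
* KNN imputation neighbours are *features* (rows), the canonical
  orientation for expression-matrix imputation, with an unweighted mean of
  the k nearest observed neighbours and Euclidean distance over columns
  observed in both features; the default k is 10.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from sklearn.impute import KNNImputer

from .layers import AnnotationTable, OmicsLayer

__all__ = [
    "filter_missing",
    "knn_impute",
    "log2p1_transform",
    "filter_by_annotation",
    "preprocess_layer",
]

logger = logging.getLogger(__name__)


def filter_missing(layer: OmicsLayer, max_missing_rate: float = 0.30) -> OmicsLayer:
    """Drop features whose missing fraction strictly exceeds the threshold.

    Survivor order is preserved. Raises if nothing survives.
    """
    if not 0 <= max_missing_rate < 1:
        raise ValueError("max_missing_rate must be in [0, 1)")
    frac = layer.missing_mask.mean(axis=1)
    keep = frac <= max_missing_rate
    if not keep.any():
        raise ValueError(
            f"layer {layer.name!r}: all {layer.n_features} features exceed "
            f"{max_missing_rate:.0%} missingness"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("layer %s: dropped %d/%d features for missingness > %.0f%%",
                    layer.name, dropped, layer.n_features, 100 * max_missing_rate)
    return layer.select_features(keep)


def knn_impute(layer: OmicsLayer, k_impute: int = 10) -> OmicsLayer:
    """Replace missing entries with the unweighted mean of the k nearest
    features (rows), nearness by Euclidean distance over shared observed
    columns. Observed entries are never modified."""
    if k_impute < 1:
        raise ValueError("k_impute must be >= 1")
    mask = layer.missing_mask
    if not mask.any():
        return replace(layer, values=layer.values.copy())
    if mask.all(axis=1).any():
        bad = layer.feature_ids[mask.all(axis=1)][:5]
        raise ValueError(
            f"layer {layer.name!r}: features with zero observed values "
            f"(e.g. {list(bad)}); run filter_missing first"
        )
    imputer = KNNImputer(n_neighbors=k_impute, weights="uniform")
    # rows are features: sklearn imputes a row's missing column from the
    # k nearest complete-in-that-column rows, exactly the convention here
    imputed = imputer.fit_transform(layer.values)
    if imputed.shape != layer.values.shape:
        raise RuntimeError("imputation unexpectedly dropped a column")
    out = layer.values.copy()
    out[mask] = imputed[mask]
    return replace(layer, values=out)


def log2p1_transform(layer: OmicsLayer) -> OmicsLayer:
    """Elementwise log2(x + 1). Input must be nonnegative."""
    vals = layer.values
    if np.nanmin(vals) < 0:
        raise ValueError(f"layer {layer.name!r}: negative values cannot be log2(x+1)-transformed")
    return replace(layer, values=np.log2(vals + 1.0))


def filter_by_annotation(
    layer: OmicsLayer,
    ann: AnnotationTable,
    promoter_window_bp: int = 2000,
    excluded_chroms: frozenset = frozenset({"chrX", "chrY"}),
) -> OmicsLayer:
    """Keep promoter-window features off the excluded chromosomes.

    Features absent from the annotation are dropped with a logged count.
    """
    if len(ann) == 0:
        raise ValueError("empty annotation table")
    tab = ann.table.set_index("feature_id")
    in_ann = np.array([f in tab.index for f in layer.feature_ids])
    n_unannotated = int((~in_ann).sum())
    if n_unannotated:
        logger.info("layer %s: dropped %d unannotated features", layer.name, n_unannotated)
    sub = tab.reindex(layer.feature_ids[in_ann])
    ok = (sub["distance_to_tss"].abs() <= promoter_window_bp) & (
        ~sub["chrom"].isin(excluded_chroms)
    )
    keep = np.zeros(layer.n_features, dtype=bool)
    keep[np.flatnonzero(in_ann)] = ok.to_numpy()
    if not keep.any():
        raise ValueError(f"layer {layer.name!r}: no features survive the annotation filter")
    return layer.select_features(keep)


def preprocess_layer(
    layer: OmicsLayer,
    max_missing_rate: float = 0.30,
    k_impute: int = 10,
    log_transform: bool = False,
    annotation: AnnotationTable | None = None,
    promoter_window_bp: int = 2000,
    excluded_chroms: frozenset = frozenset({"chrX", "chrY"}),
) -> OmicsLayer:
    """Standard per-layer pipeline: optional annotation filter, missingness
    filter, KNN imputation, optional log2(x+1)."""
    if annotation is not None:
        layer = filter_by_annotation(layer, annotation, promoter_window_bp, excluded_chroms)
    layer = filter_missing(layer, max_missing_rate)
    layer = knn_impute(layer, k_impute)
    if log_transform:
        layer = log2p1_transform(layer)
    return layer
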