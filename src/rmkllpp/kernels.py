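"""Per-omics Gaussian kernels and their convex combination.

Each omics layer contributes several Gaussian kernels
``K(i, j) = exp(-gamma * ||x_i - x_j||^2)`` at bandwidths spread around the
median heuristic (base gamma = 1 / (2 * median pairwise distance squared)),
letting the kernel weights select the relevant scale per data type. Every
kernel is cosine-normalized to unit diagonal so no layer dominates the
composite through sheer scale; this keeps each Gaussian kernel strictly
positive definite (double-centering, available as an option, makes every
kernel singular and leaks constraint-nullspace noise into the embedding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .layers import OmicsLayer

__all__ = [
    "KernelSet",
    "KernelWeights",
    "gaussian_kernel",
    "default_gammas",
    "center_and_normalize",
    "cosine_normalize",
    "combine_kernels",
    "kernels_from_layers",
]

DEFAULT_BANDWIDTH_FACTORS = (0.5, 1.0, 2.0)


@dataclass
class KernelWeights:
    """Simplex-constrained kernel weight vector beta."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 1:
            raise ValueError("beta must be a vector")
        if (self.beta < -1e-12).any():
            raise ValueError("beta entries must be nonnegative")
        s = self.beta.sum()
        if abs(s - 1.0) > 1e-10:
            raise ValueError(f"beta must sum to 1 (got {s})")

    @classmethod
    def uniform(cls, m: int) -> "KernelWeights":
        return cls(np.full(m, 1.0 / m))

    def __len__(self) -> int:
        return len(self.beta)


@dataclass
class KernelSet:
    """Same-ordered N x N similarity matrices with provenance.

    ``provenance[m]`` is a ``(layer_name, gamma)`` pair recording where
    kernel m came from.
    """

    kernels: list
    sample_ids: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n = len(self.sample_ids)
        ks = []
        for i, k in enumerate(self.kernels):
            k = np.asarray(k, dtype=float)
            if k.shape != (n, n):
                raise ValueError(f"kernel {i} has shape {k.shape}, expected ({n}, {n})")
            if np.abs(k - k.T).max() > 1e-10:
                raise ValueError(f"kernel {i} is not symmetric")
            ks.append((k + k.T) / 2.0)  # absorb float asymmetry
        self.kernels = ks
        if not self.provenance:
            self.provenance = [("unknown", float("nan"))] * len(ks)
        if len(self.provenance) != len(ks):
            raise ValueError("provenance length mismatch")

    @property
    def n_kernels(self) -> int:
        return len(self.kernels)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def stacked(self) -> np.ndarray:
        """(M, N, N) array view of the kernel list."""
        return np.stack(self.kernels)


def gaussian_kernel(layer: OmicsLayer, gamma: float) -> np.ndarray:
    """K(i, j) = exp(-gamma * ||x_i - x_j||^2) over the layer's features."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if not layer.is_complete():
        raise ValueError(f"layer {layer.name!r} has missing entries; impute first")
    d2 = squareform(pdist(layer.values.T, metric="sqeuclidean"))
    k = np.exp(-gamma * d2)
    return (k + k.T) / 2.0


def default_gammas(layer: OmicsLayer, factors=DEFAULT_BANDWIDTH_FACTORS) -> list:
    """Median-heuristic bandwidths: base gamma = 1 / (2 d~^2) with d~ the
    median pairwise Euclidean distance, scaled by each factor."""
    if layer.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = pdist(layer.values.T, metric="euclidean")
    med = float(np.median(d))
    if med == 0:
        raise ValueError(f"layer {layer.name!r}: all samples identical (median distance 0)")
    base = 1.0 / (2.0 * med**2)
    return [base * f for f in factors]


def center_and_normalize(kernel: np.ndarray) -> np.ndarray:
    """Double-center in feature space, then cosine-normalize to unit diagonal.

    Centering: K <- K - 1K/N - K1/N + 1K1/N^2 (mean removal in the implicit
    feature space); normalization: K(i,j) / sqrt(K(i,i) K(j,j)).
    """
    k = np.asarray(kernel, dtype=float)
    n = k.shape[0]
    row_mean = k.mean(axis=0, keepdims=True)
    col_mean = k.mean(axis=1, keepdims=True)
    total = k.mean()
    kc = k - row_mean - col_mean + total
    diag = np.diag(kc).copy()
    if (diag <= 1e-14 * max(1.0, np.abs(kc).max())).any():
        raise ValueError("degenerate kernel: zero diagonal after centering")
    scale = np.sqrt(diag)
    kn = kc / np.outer(scale, scale)
    np.fill_diagonal(kn, 1.0)
    return (kn + kn.T) / 2.0


def combine_kernels(ks: KernelSet, w: KernelWeights) -> np.ndarray:
    """Composite kernel K = sum_m beta_m K_m."""
    if len(w) != ks.n_kernels:
        raise ValueError(f"{len(w)} weights for {ks.n_kernels} kernels")
    return np.einsum("m,mij->ij", w.beta, ks.stacked())


def cosine_normalize(kernel: np.ndarray) -> np.ndarray:
    """Cosine normalization K(i,j) / sqrt(K(i,i) K(j,j)) to unit diagonal."""
    k = np.asarray(kernel, dtype=float)
    diag = np.diag(k).copy()
    if (diag <= 0).any():
        raise ValueError("cosine normalization needs a positive diagonal")
    scale = np.sqrt(diag)
    kn = k / np.outer(scale, scale)
    np.fill_diagonal(kn, 1.0)
    return (kn + kn.T) / 2.0


def kernels_from_layers(
    layers,
    bandwidth_factors=DEFAULT_BANDWIDTH_FACTORS,
    conditioning: str = "cosine",
) -> KernelSet:
    """Build the full kernel stack: per layer, one Gaussian kernel per
    bandwidth factor around the median heuristic, conditioned so every
    kernel has unit diagonal.

    ``conditioning`` is one of ``"cosine"`` (default; a no-op for Gaussian
    kernels, whose diagonal is already 1, and the choice that keeps every
    kernel strictly positive definite), ``"center"`` (double-centering plus
    cosine normalization — note centering makes each kernel singular, which
    degrades the embedding; see the methods note) or ``"none"``."""
    layers = list(layers)
    if not layers:
        raise ValueError("no layers given")
    sample_ids = layers[0].sample_ids
    for lay in layers[1:]:
        if not np.array_equal(lay.sample_ids, sample_ids):
            raise ValueError(f"layer {lay.name!r}: sample ids differ from first layer")
    if conditioning not in ("cosine", "center", "none"):
        raise ValueError(f"unknown conditioning {conditioning!r}")
    kernels, provenance = [], []
    for lay in layers:
        for gamma in default_gammas(lay, bandwidth_factors):
            k = gaussian_kernel(lay, gamma)
            if conditioning == "cosine":
                k = cosine_normalize(k)
            elif conditioning == "center":
                k = center_and_normalize(k)
            kernels.append(k)
            provenance.append((lay.name, gamma))
    return KernelSet(kernels, sample_ids, provenance)
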