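"""Synthetic multi-omics cohorts with planted subtypes and survival.

The generator emulates the statistical structure the subtyping pipeline
assumes: several omics layers observed on the same samples, a latent
subtype partition that shifts the means of a subset of "informative"
features, missing-completely-at-random entries, and subtype-dependent
exponential survival with independent right censoring.

Value models
------------
``gaussian``
    The latent Gaussian signal is emitted directly (unit within-subtype sd).
``expression-counts``
    Log-normal counts: ``exp(base + signal)`` with a per-feature base level,
    so values are nonnegative and log2(x+1)-transformable.
``methylation-beta``
    Gaussian on the logit scale mapped through the inverse logit, so values
    stay strictly inside (0, 1).

Informative features shift one subtype's mean by ``effect_size`` latent
standard deviations (the shifted subtype cycles through features, so every
subtype is marked by ~``n_informative / n_subtypes`` features).

A single cohort seed expands into per-layer substreams via
``numpy.random.SeedSequence``, so adding a layer never perturbs the draws
of earlier layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .layers import AnnotationTable, OmicsLayer

__all__ = [
    "LayerSpec",
    "SurvivalSpec",
    "CohortSpec",
    "reference_cohort_spec",
    "generate_labels",
    "generate_multiomics",
    "generate_survival",
    "generate_annotation",
]

_VALUE_MODELS = ("gaussian", "expression-counts", "methylation-beta")


@dataclass
class LayerSpec:
    """Recipe for one synthetic omics layer."""

    name: str
    n_features: int
    n_informative: int
    effect_size: float
    value_model: str = "gaussian"
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ValueError(f"layer {self.name!r}: n_features must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError(f"layer {self.name!r}: n_informative out of range")
        if self.effect_size < 0:
            raise ValueError(f"layer {self.name!r}: effect_size must be >= 0")
        if self.value_model not in _VALUE_MODELS:
            raise ValueError(
                f"layer {self.name!r}: unknown value_model {self.value_model!r}; "
                f"choose from {_VALUE_MODELS}"
            )
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"layer {self.name!r}: missing_rate must be in [0, 1)")


@dataclass
class SurvivalSpec:
    """Subtype-dependent exponential survival with independent censoring.

    Event times are exponential with hazard
    ``baseline_hazard * exp(log_hazard_per_subtype[label])``; subtype 0 is
    the reference (log-hazard 0 by convention of the first entry).
    """

    baseline_hazard: float = 1.0 / 1000.0
    log_hazard_per_subtype: tuple = (0.0,)
    censoring_rate: float = 0.3
    time_unit: str = "days"

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")


@dataclass
class CohortSpec:
    """Full synthetic cohort description."""

    n_samples: int = 150
    subtype_proportions: tuple = (1 / 3, 1 / 3, 1 / 3)
    layer_specs: list = field(default_factory=list)
    survival_spec: SurvivalSpec = field(default_factory=SurvivalSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.subtype_proportions, dtype=float)
        if p.ndim != 1 or len(p) < 1 or (p < 0).any():
            raise ValueError("subtype_proportions must be a nonnegative vector")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"subtype_proportions sum to {p.sum()}, not 1")
        if self.n_samples < len(p):
            raise ValueError("n_samples must be >= number of subtypes")

    @property
    def n_subtypes(self) -> int:
        return len(self.subtype_proportions)


def reference_cohort_spec(
    seed: int,
    n_samples: int = 150,
    effect_size: float = 2.5,
    missing_rate: float = 0.02,
    log_hazard_per_subtype: tuple = (0.0, 0.0, 1.5),
) -> CohortSpec:
    """Reference synthetic cohort: three equal subtypes, one informative
    mRNA-like count layer, an uninformative miRNA-like count layer and an
    uninformative methylation layer, with light MCAR missingness. Survival
    follows the null-groups-plus-one-high-risk pattern (two subtypes share
    the baseline hazard, the third carries log-HR 1.5), so survival-based
    merging collapses the null pair and isolates the high-risk subtype."""
    return CohortSpec(
        n_samples=n_samples,
        subtype_proportions=(1 / 3, 1 / 3, 1 / 3),
        layer_specs=[
            LayerSpec("mrna", 400, 80, effect_size, "expression-counts", missing_rate),
            LayerSpec("mirna", 100, 0, 0.0, "expression-counts", missing_rate),
            LayerSpec("methylation", 400, 0, 0.0, "methylation-beta", missing_rate),
        ],
        survival_spec=SurvivalSpec(
            baseline_hazard=1 / 1500,
            log_hazard_per_subtype=log_hazard_per_subtype,
            censoring_rate=0.3,
        ),
        seed=seed,
    )


def _largest_remainder_counts(proportions: np.ndarray, n: int) -> np.ndarray:
    """Integer group sizes summing to n, closest to n * proportions."""
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def generate_labels(spec: CohortSpec) -> np.ndarray:
    """Planted subtype labels (0-based), exact rounded group sizes, shuffled
    deterministically under the cohort seed."""
    p = np.asarray(spec.subtype_proportions, dtype=float)
    counts = _largest_remainder_counts(p, spec.n_samples)
    labels = np.repeat(np.arange(len(p)), counts)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    rng.shuffle(labels)
    return labels


def _latent_signal(
    labels: np.ndarray, n_features: int, n_informative: int, effect: float, rng
) -> np.ndarray:
    """Unit-sd Gaussian matrix (features x samples) with subtype mean shifts.

    Informative feature f marks subtype (f mod S): that subtype's mean is
    shifted by `effect` latent sd units; all other means are 0.
    """
    n = len(labels)
    z = rng.standard_normal((n_features, n))
    if n_informative and effect > 0:
        n_sub = int(labels.max()) + 1
        marked = np.arange(n_informative) % n_sub  # feature -> shifted subtype
        shift = effect * (labels[None, :] == marked[:, None])
        z[:n_informative] += shift
    return z


def _generate_layer(spec: LayerSpec, labels: np.ndarray, seed_seq) -> OmicsLayer:
    rng = np.random.default_rng(seed_seq)
    z = _latent_signal(labels, spec.n_features, spec.n_informative, spec.effect_size, rng)
    if spec.value_model == "gaussian":
        values = z
    elif spec.value_model == "expression-counts":
        base = rng.normal(3.0, 1.0, size=(spec.n_features, 1))
        values = np.exp(base + z)
    else:  # methylation-beta
        base = rng.normal(0.0, 1.5, size=(spec.n_features, 1))
        values = special.expit(base + z)
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = values.astype(float)
        values[mask] = np.nan
    feature_ids = np.array([f"{spec.name}_f{i:05d}" for i in range(spec.n_features)], dtype=object)
    sample_ids = np.array([f"S{i:04d}" for i in range(len(labels))], dtype=object)
    return OmicsLayer(spec.name, values, feature_ids, sample_ids)


def generate_multiomics(spec: CohortSpec) -> tuple[list[OmicsLayer], np.ndarray]:
    """Generate all layers of a cohort plus the true subtype labels.

    Returns
    -------
    layers : list of OmicsLayer
        Shared sample ordering across layers.
    labels : ndarray of int
        Planted subtype per sample (0-based).
    """
    labels = generate_labels(spec)
    layers = []
    for i, lspec in enumerate(spec.layer_specs):
        layers.append(_generate_layer(lspec, labels, np.random.SeedSequence([spec.seed, i + 1])))
    return layers, labels


def _censoring_hazard(spec: SurvivalSpec, labels: np.ndarray) -> float:
    """Censoring hazard c such that the expected censored fraction matches
    spec.censoring_rate: for exponential T (rate lam) and C (rate c),
    P(C < T) = c / (c + lam); solve the group-size-weighted mean for c."""
    lhr = np.asarray(spec.log_hazard_per_subtype, dtype=float)
    lam = spec.baseline_hazard * np.exp(lhr)
    counts = np.bincount(labels, minlength=len(lhr)).astype(float)
    weights = counts / counts.sum()

    target = spec.censoring_rate

    def expected_censored(c):
        return float(np.sum(weights * c / (c + lam))) - target

    if target == 0:
        return 0.0
    # bracket: c -> 0 gives 0, c -> inf gives 1
    hi = lam.max()
    while expected_censored(hi) < 0:
        hi *= 10
    return optimize.brentq(expected_censored, 1e-12 * lam.min(), hi)


def generate_survival(labels: np.ndarray, spec: SurvivalSpec, seed: int) -> pd.DataFrame:
    """Exponential event times per planted subtype with independent censoring.

    Returns a data frame with columns ``sample_id``, ``time``, ``event``
    (1 = death observed, 0 = censored).
    """
    labels = np.asarray(labels)
    lhr = np.asarray(spec.log_hazard_per_subtype, dtype=float)
    if labels.max() >= len(lhr):
        raise ValueError("labels index beyond log_hazard_per_subtype")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    lam = spec.baseline_hazard * np.exp(lhr[labels])
    t_event = rng.exponential(1.0 / lam)
    if spec.censoring_rate > 0:
        c = _censoring_hazard(spec, labels)
        t_cens = rng.exponential(1.0 / c, size=len(labels))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(len(labels), dtype=int)
    # exponential draws are strictly positive a.s.; clip guards exact zeros
    time = np.maximum(time, np.finfo(float).tiny)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(len(labels))],
            "time": time,
            "event": event,
        }
    )


def generate_clinical(
    labels: np.ndarray, spec: SurvivalSpec, seed: int
) -> pd.DataFrame:
    """Survival table plus subtype-independent clinical covariates
    (age, gender, pathologic stage) for covariate-adjusted models."""
    surv = generate_survival(labels, spec, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 131]))
    n = len(surv)
    surv["age"] = np.round(rng.normal(58.6, 13.0, size=n), 1)
    surv["gender"] = rng.choice(["female", "male"], size=n, p=[0.32, 0.68])
    surv["stage"] = rng.choice(
        ["I", "II", "III", "IV"], size=n, p=[0.52, 0.25, 0.21, 0.02]
    )
    return surv


def generate_annotation(
    n_cpg: int,
    fraction_promoter: float,
    fraction_sex_chrom: float,
    seed: int,
    promoter_window_bp: int = 2000,
    feature_ids=None,
) -> AnnotationTable:
    """BED-like annotation with exact category counts.

    ``round(fraction_sex_chrom * n_cpg)`` features land on chrX/chrY
    (alternating) and ``round(fraction_promoter * n_cpg)`` get
    |distance_to_tss| <= promoter_window_bp; the two categories are
    assigned independently (and may overlap) so both counts are exact.
    """
    if not 0 <= fraction_promoter <= 1 or not 0 <= fraction_sex_chrom <= 1:
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 211]))
    n_sex = round(fraction_sex_chrom * n_cpg)
    n_prom = round(fraction_promoter * n_cpg)
    chroms = np.array(
        [("chrX" if i % 2 == 0 else "chrY") for i in range(n_sex)]
        + [f"chr{(i % 22) + 1}" for i in range(n_cpg - n_sex)],
        dtype=object,
    )
    dist = np.empty(n_cpg, dtype=int)
    signs = rng.choice([-1, 1], size=n_cpg)
    dist[:n_prom] = signs[:n_prom] * rng.integers(0, promoter_window_bp + 1, size=n_prom)
    dist[n_prom:] = signs[n_prom:] * rng.integers(
        promoter_window_bp + 1, 50_001, size=n_cpg - n_prom
    )
    if feature_ids is None:
        feature_ids = [f"cg{i:06d}" for i in range(n_cpg)]
    table = pd.DataFrame(
        {
            "chrom": chroms,
            "position": rng.integers(0, 100_000_000, size=n_cpg),
            "feature_id": list(feature_ids),
            "distance_to_tss": dist,
        }
    )
    return AnnotationTable(table)
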