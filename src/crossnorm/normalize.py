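"""Normalization schemes, including the NDEG-referenced variants.

Nine methods are exposed through :func:`normalize`:

==============  ==============================================================
LOG             log2(x + pseudo_count)
Z               per-gene standardization (population SD; constant rows -> 0)
NST             per-gene rank -> percentile -> inverse standard-normal CDF
NPN             as NST with a selectable target (normal or uniform percentiles)
QN              classic column-wise quantile normalization over all genes
LOG_RQN         LOG, then quantile-map every gene onto the NDEG-derived target
LOG_RQN_Z       LOG_RQN followed by Z
LOG_NPN_Z       LOG, percentile-map onto the NDEG target, then Z
LOG_NICG_Z      LOG, subtract each sample's mean over NDEG rows, then Z
==============  ==============================================================

The reference-based methods fit a target distribution from the reference
(NDEG) genes only: per sample the reference values are sorted and averaged
across samples at each sorted position.  Applying the target maps each
sample's values at fractional percentile u = (rank - 0.5)/G onto the target's
empirical quantile function, whose node j of m sits at (j - 0.5)/m, with
linear interpolation and end clamping.  This is what makes two independently
normalized platforms comparable: the anchor is the shared NDEG set, not any
cross-platform fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from crossnorm.core_io import DataError, ExpressionMatrix
from crossnorm.selection import GeneSelection

METHODS = ("RAW", "LOG", "Z", "NST", "NPN", "QN", "LOG_RQN", "LOG_RQN_Z", "LOG_NPN_Z", "LOG_NICG_Z")
REFERENCE_METHODS = ("LOG_RQN", "LOG_RQN_Z", "LOG_NPN_Z", "LOG_NICG_Z")


@dataclass
class NormalizationSpec:
    """A normalization method plus its parameters.

    ``reference_genes`` may be given explicitly; otherwise :func:`normalize`
    takes the NDEG list from the supplied :class:`GeneSelection`.
    """

    method: str
    pseudo_count: float = 1.0
    reference_genes: list[str] | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise DataError(f"unknown normalization method {self.method!r}")
        if self.pseudo_count <= 0:
            raise DataError("pseudo_count must be positive")
        if self.reference_genes is not None and not self.reference_genes:
            raise DataError("reference_genes must be non-empty when given")


@dataclass
class FittedNormalizer:
    """Reference-gene quantile target fitted on one matrix."""

    reference_genes: list[str]
    target: np.ndarray = field(repr=False)  # sorted, non-decreasing, length m


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------

def log_transform(x: ExpressionMatrix, pseudo_count: float = 1.0) -> ExpressionMatrix:
    """value -> log2(value + pseudo_count); flags the result as log scale."""
    v = x.values
    if np.nanmin(v) < 0:
        raise DataError("negative values: input looks already log-scaled")
    if pseudo_count <= 0:
        raise DataError("pseudo_count must be positive")
    return x.with_values(np.log2(v + pseudo_count), scale="log")


def zscore(x: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene (row) standardization with population SD; constant rows -> 0."""
    if x.n_samples < 2:
        raise DataError("zscore needs at least 2 samples")
    v = x.values
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=0, keepdims=True)
    out = np.divide(v - mu, sd, out=np.zeros_like(v), where=sd > 0)
    return x.with_values(out)


def _row_percentiles(v: np.ndarray) -> np.ndarray:
    """Average ranks within each row, mapped to rank/(n+1)."""
    n = v.shape[1]
    ranks = np.apply_along_axis(stats.rankdata, 1, v)  # average ranks, 1..n
    return ranks / (n + 1)


def normal_scores(x: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene rank -> percentile rank/(n+1) -> inverse standard-normal CDF."""
    if x.n_samples < 2:
        raise DataError("normal_scores needs at least 2 samples")
    return x.with_values(stats.norm.ppf(_row_percentiles(x.values)))


def npn(x: ExpressionMatrix, target: str = "normal") -> ExpressionMatrix:
    """Nonparanormal transform: ranks -> percentiles -> target distribution.

    ``target="normal"`` is identical to :func:`normal_scores`;
    ``target="uniform"`` returns the percentiles themselves.
    """
    if target == "normal":
        return normal_scores(x)
    if target == "uniform":
        if x.n_samples < 2:
            raise DataError("npn needs at least 2 samples")
        return x.with_values(_row_percentiles(x.values))
    raise DataError(f"unknown npn target {target!r}")


def quantile_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Classic column-wise quantile normalization.

    Each rank position's target is the cross-sample mean of position-sorted
    values; within-column ties receive the mean of their tied target
    positions, so identical inputs map to identical outputs.
    """
    v = x.values
    target = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        out[:, j] = _map_column_to_target_positions(v[:, j], target)
    return x.with_values(out)


def _map_column_to_target_positions(col: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Assign target[position] by within-column rank; tie groups get the mean target."""
    order = np.argsort(col, kind="stable")
    sorted_col = col[order]
    _, inverse = np.unique(sorted_col, return_inverse=True)
    sums = np.bincount(inverse, weights=target)
    counts = np.bincount(inverse)
    out = np.empty_like(col)
    out[order] = (sums / counts)[inverse]
    return out


# ---------------------------------------------------------------------------
# reference-gene (NDEG) methods
# ---------------------------------------------------------------------------

def fit_reference_target(x: ExpressionMatrix, reference_genes) -> FittedNormalizer:
    """Quantile-average the reference rows: the RQN/NPN-ref target distribution."""
    reference_genes = list(reference_genes)
    if not reference_genes:
        raise DataError("empty reference gene set")
    ref = x.subset_genes(reference_genes)
    target = np.sort(ref.values, axis=0).mean(axis=1)
    return FittedNormalizer(reference_genes, target)


def apply_rqn(x: ExpressionMatrix, fitted: FittedNormalizer) -> ExpressionMatrix:
    """Map every gene of every sample onto the reference quantile target.

    Per sample column over all G genes: fractional percentile
    u = (rank - 0.5)/G with average ranks for ties, then linear interpolation
    of the target's empirical quantile function (node j of m at (j - 0.5)/m),
    clamping u beyond the end nodes.
    """
    m = len(fitted.target)
    if m < 2:
        raise DataError("reference target needs at least 2 genes for interpolation")
    v = x.values
    g = v.shape[0]
    u_nodes = (np.arange(1, m + 1) - 0.5) / m
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        u = (stats.rankdata(v[:, j]) - 0.5) / g
        out[:, j] = np.interp(u, u_nodes, fitted.target)
    return x.with_values(out)


def apply_npn_reference(x: ExpressionMatrix, fitted: FittedNormalizer) -> ExpressionMatrix:
    """Percentile-map all genes onto the reference distribution.

    Mechanically identical to :func:`apply_rqn`; kept as a distinct named
    step because it is composed differently (always inside LOG_NPN_Z).
    """
    return apply_rqn(x, fitted)


def nicg_scale(x_log: ExpressionMatrix, reference_genes) -> ExpressionMatrix:
    """Internal-control-gene scaling: subtract the per-sample reference mean.

    Operates in log space (subtraction there is division on the linear
    scale), so the input must be flagged as log scale.
    """
    if x_log.scale != "log":
        raise DataError("nicg_scale requires log-scale input")
    reference_genes = list(reference_genes)
    if not reference_genes:
        raise DataError("empty reference gene set")
    ref_mean = x_log.subset_genes(reference_genes).values.mean(axis=0)
    return x_log.with_values(x_log.values - ref_mean[None, :])


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def normalize(
    x: ExpressionMatrix,
    spec: NormalizationSpec,
    selection: GeneSelection | None = None,
) -> ExpressionMatrix:
    """Apply a normalization method, resolving composites.

    Reference-based methods use ``spec.reference_genes`` if set, else the
    NDEG list of ``selection``.
    """
    method = spec.method
    if method == "RAW":
        return x.with_values(x.values.copy())
    if method == "LOG":
        return log_transform(x, spec.pseudo_count)
    if method == "Z":
        return zscore(x)
    if method == "NST":
        return normal_scores(x)
    if method == "NPN":
        return npn(x, target="normal")
    if method == "QN":
        return quantile_normalize(x)

    refs = spec.reference_genes
    if refs is None:
        if selection is None or not selection.ndeg:
            raise DataError(f"{method} requires a non-empty NDEG reference set")
        refs = selection.ndeg

    logged = log_transform(x, spec.pseudo_count)
    if method == "LOG_RQN":
        return apply_rqn(logged, fit_reference_target(logged, refs))
    if method == "LOG_RQN_Z":
        return zscore(apply_rqn(logged, fit_reference_target(logged, refs)))
    if method == "LOG_NPN_Z":
        return zscore(apply_npn_reference(logged, fit_reference_target(logged, refs)))
    if method == "LOG_NICG_Z":
        return zscore(nicg_scale(logged, refs))
    raise DataError(f"unknown normalization method {method!r}")  # pragma: no cover
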