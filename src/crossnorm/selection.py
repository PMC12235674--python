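"""Per-gene one-way ANOVA and threshold-based DEG/NDEG selection.

For each gene the F statistic compares between-class to within-class variance,

    F = MSB / MSW,   MSB = SSB/(k-1),   MSW = SSW/(N-k),

with the p-value taken from the upper tail of the F(k-1, N-k) distribution.
Genes with p below a low threshold are differentially expressed (DEG, the
classifier features); genes with p above a high threshold are treated as
non-differentially expressed (NDEG) and serve as normalization references,
the transcriptome analogue of housekeeping genes.  Thresholding is strict
(p < tau_deg, p > tau_ndeg); boundary ties are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from crossnorm.core_io import DataError, ExpressionMatrix, SubtypeLabels

#: DEG p-value threshold grid (the experiment's tuning axis; 1 = keep all genes)
DEG_TAU_GRID = tuple(round(0.001 * i, 3) for i in range(1, 11)) + (0.02, 0.03, 0.05, 0.07, 0.1, 1.0)
#: NDEG p-value threshold grid
NDEG_TAU_GRID = (0.85, 0.90, 0.92, 0.95, 0.98)


def anova_f(values_by_group) -> tuple[float, float]:
    """One-way ANOVA F and upper-tail p for one gene.

    Degenerate cases follow the selection semantics rather than erroring:
    zero within-group variance with distinct group means gives (inf, 0); a
    fully constant gene gives (0, 1) so it stays eligible as an NDEG.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    if len(groups) < 2:
        raise DataError("ANOVA needs at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise DataError("ANOVA group with no observations")
    k = len(groups)
    n = sum(g.size for g in groups)
    if n <= k:
        raise DataError(f"ANOVA needs N > k (N={n}, k={k})")

    allv = np.concatenate(groups)
    if allv.max() == allv.min():  # constant gene
        return 0.0, 1.0
    grand = allv.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if all(g.max() == g.min() for g in groups):  # exact zero within-group variance
        return float("inf"), 0.0
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return float(f), float(stats.f.sf(f, k - 1, n - k))


def anova_table(x: ExpressionMatrix, labels: SubtypeLabels, fdr: bool = False) -> pd.DataFrame:
    """Vectorized per-gene ANOVA over a matrix; returns gene_id-indexed F, p (, q).

    Every sample of ``x`` must be labelled.  Constant genes get (F=0, p=1);
    genes with zero within-class variance but distinct class means get
    (F=inf, p=0).  With ``fdr`` the Benjamini-Hochberg step-up adjustment of
    the p vector is added as ``q``.
    """
    y = labels.y(x.sample_ids)
    classes, inv = np.unique(y, return_inverse=True)
    k = len(classes)
    if k < 2:
        raise DataError("ANOVA needs at least 2 classes among the samples")
    v = x.values
    n = v.shape[1]
    if n <= k:
        raise DataError(f"ANOVA needs N > k (N={n}, k={k})")

    grand = v.mean(axis=1)
    ssb = np.zeros(v.shape[0])
    ssw = np.zeros(v.shape[0])
    within_const = np.ones(v.shape[0], dtype=bool)
    for c in range(k):
        vc = v[:, inv == c]
        mc = vc.mean(axis=1)
        ssb += vc.shape[1] * (mc - grand) ** 2
        ssw += ((vc - mc[:, None]) ** 2).sum(axis=1)
        within_const &= vc.max(axis=1) == vc.min(axis=1)
    const = v.max(axis=1) == v.min(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    f[within_const & ~const] = np.inf
    f[const] = 0.0
    p = stats.f.sf(f, k - 1, n - k)
    p[const] = 1.0

    table = pd.DataFrame({"F": f, "p": p}, index=pd.Index(x.gene_ids, name="gene_id"))
    if fdr:
        table["q"] = benjamini_hochberg(p)
    return table


def benjamini_hochberg(p) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, q >= p elementwise)."""
    return stats.false_discovery_control(np.asarray(p, dtype=float), method="bh")


@dataclass
class GeneSelection:
    """DEG/NDEG gene lists together with the thresholds that produced them."""

    deg: list[str]
    ndeg: list[str]
    tau_deg: float
    tau_ndeg: float
    mode: str = "p"  # "p" (raw p-values) or "q" (BH-adjusted)


def select_genes(
    table: pd.DataFrame,
    tau_deg: float,
    tau_ndeg: float,
    mode: str = "p",
    require_ndeg: bool = False,
) -> GeneSelection:
    """Select DEG (p < tau_deg) and NDEG (p > tau_ndeg) with strict inequalities.

    Gene order of the table is preserved.  An empty NDEG set is a hard error
    only when the caller declares that a reference-based normalization will
    need it (``require_ndeg``); otherwise it is a warning.
    """
    if not (0 < tau_deg <= 1) or not (0 <= tau_ndeg < 1):
        raise DataError(f"thresholds out of range: tau_deg={tau_deg}, tau_ndeg={tau_ndeg}")
    if mode not in ("p", "q"):
        raise DataError(f"unknown selection mode {mode!r}")
    if mode == "q" and "q" not in table.columns:
        raise DataError("mode 'q' requires an FDR-adjusted table (anova_table(..., fdr=True))")
    crit = table[mode].to_numpy()
    deg = list(table.index[crit < tau_deg])
    ndeg = list(table.index[crit > tau_ndeg])
    if not ndeg:
        msg = f"no NDEG at tau_ndeg={tau_ndeg} (mode {mode})"
        if require_ndeg:
            raise DataError(msg)
        warnings.warn(msg, stacklevel=2)
    return GeneSelection(deg, ndeg, tau_deg, tau_ndeg, mode)
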