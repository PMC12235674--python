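"""Data model, delimited-text readers/writers, and the cleaning/matching step.

Expression data are genes-in-rows, samples-in-columns delimited text with one
header row of sample IDs and the gene ID in the first column.  Labels are a
two-column table (sample ID, subtype).  Cleaning retains labelled samples,
intersects the gene universes of the two platforms, and drops any gene with a
missing value on either platform, leaving two matrices with an identical gene
axis ready for selection and normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("crossnorm")

#: tokens treated as a missing measurement (case-insensitive, after stripping)
MISSING_TOKENS = frozenset({"", "na", "nan", "null"})


class DataError(ValueError):
    """Raised when input data violate a structural precondition."""


def _check_unique(ids, axis: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate {axis} ID: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued matrix with identity and scale metadata.

    Parameters
    ----------
    data
        DataFrame indexed by gene ID with sample IDs as columns.  Missing
        measurements are NaN (only permitted before cleaning).
    platform
        Free-text platform tag, e.g. ``"microarray"`` or ``"rnaseq"``.
    scale
        ``"linear"`` for intensity/count-like values, ``"log"`` after a log
        transform.  Reference-gene centering requires log scale.
    """

    data: pd.DataFrame
    platform: str = ""
    scale: str = "linear"

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")

    # -- identity -----------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    # -- derivation ---------------------------------------------------------
    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise DataError(f"unknown gene IDs: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.platform, self.scale)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise DataError(f"unknown sample IDs: {missing[:5]}")
        return ExpressionMatrix(self.data[list(sample_ids)], self.platform, self.scale)

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "ExpressionMatrix":
        """Same gene/sample identity, new value matrix (used by transforms)."""
        if values.shape != self.data.shape:
            raise DataError(f"shape mismatch: {values.shape} vs {self.data.shape}")
        df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return ExpressionMatrix(df, self.platform, self.scale if scale is None else scale)


@dataclass
class SubtypeLabels:
    """Mapping sample ID -> class label with a fixed class order."""

    labels: pd.Series  # index: sample IDs; values: class labels
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        _check_unique(self.labels.index, "sample")

    @classmethod
    def from_mapping(cls, mapping, class_order=None) -> "SubtypeLabels":
        s = pd.Series(dict(mapping), dtype=object)
        if class_order is None:
            class_order = tuple(sorted(set(s)))
        if len(set(s)) < 2:
            raise DataError("labels must contain at least 2 distinct classes")
        return cls(s, tuple(class_order))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def restrict(self, sample_ids) -> "SubtypeLabels":
        keep = [s for s in sample_ids if s in self.labels.index]
        return SubtypeLabels(self.labels.loc[keep], self.class_order)

    def y(self, sample_ids) -> np.ndarray:
        """Class labels for the given samples, in order."""
        missing = [s for s in sample_ids if s not in self.labels.index]
        if missing:
            raise DataError(f"unlabelled samples: {missing[:5]}")
        return self.labels.loc[list(sample_ids)].to_numpy(dtype=object)

    def class_counts(self, sample_ids=None) -> dict[str, int]:
        sub = self.labels if sample_ids is None else self.labels.loc[list(sample_ids)]
        vc = sub.value_counts()
        return {c: int(vc.get(c, 0)) for c in self.class_order}


@dataclass
class CleanedPair:
    """Two cleaned matrices with identical gene axes plus their labels."""

    matrix_a: ExpressionMatrix
    matrix_b: ExpressionMatrix
    labels: SubtypeLabels
    dropped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix_a.gene_ids != self.matrix_b.gene_ids:
            raise DataError("cleaned matrices must share an identical gene order")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path, platform: str = "", scale: str = "linear") -> ExpressionMatrix:
    """Read a delimited expression matrix, preserving missing values as NaN.

    The delimiter is chosen from the extension (``.csv`` -> comma, anything
    else -> tab).  Empty cells and the tokens NA/NaN/null (any case) are
    treated as missing; any other non-numeric cell is a hard error naming the
    offending gene and sample.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    _check_unique(raw.index, "gene")
    _check_unique(raw.columns, "sample")

    stripped = raw.apply(lambda col: col.str.strip())
    miss = stripped.apply(lambda col: col.str.lower().isin(MISSING_TOKENS))
    numeric = stripped.mask(miss).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~miss
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric value {stripped.iat[i, j]!r} at gene {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r}"
        )
    return ExpressionMatrix(numeric.astype(float), platform=platform, scale=scale)


def write_expression(x: ExpressionMatrix, path) -> None:
    path = Path(path)
    x.data.to_csv(path, sep=_sep_for(path), index_label="gene_id")


_HEADER_HINTS_FIRST = {"sample", "sample_id", "sampleid", "id"}
_HEADER_HINTS_SECOND = {"label", "subtype", "class", "group"}


def read_labels(path, class_order=None) -> SubtypeLabels:
    """Read a two-column (sample ID, label) table; a header row is auto-detected."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str, keep_default_na=False)
    if df.shape[1] != 2:
        raise DataError(f"label file must have exactly 2 columns, got {df.shape[1]}")
    first, second = str(df.iat[0, 0]).strip().lower(), str(df.iat[0, 1]).strip().lower()
    if first in _HEADER_HINTS_FIRST or second in _HEADER_HINTS_SECOND:
        df = df.iloc[1:]
    mapping = {}
    for sid, lab in zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()):
        if sid in mapping:
            raise DataError(f"duplicate sample ID: {sid!r}")
        mapping[sid] = lab
    return SubtypeLabels.from_mapping(mapping, class_order=class_order)


def write_labels(labels: SubtypeLabels, path) -> None:
    path = Path(path)
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.labels.to_numpy()}).to_csv(
        path, sep=_sep_for(path), index=False
    )


# ---------------------------------------------------------------------------
# cleaning / matching
# ---------------------------------------------------------------------------

def clean_and_match(
    raw_a: ExpressionMatrix, raw_b: ExpressionMatrix, labels: SubtypeLabels
) -> CleanedPair:
    """Produce two aligned, fully-observed, labelled matrices.

    Per matrix independently, keeps only samples carrying a label.  Keeps only
    genes present on both platforms, then drops every gene with one or more
    missing values in either matrix.  Both matrices are reordered to a common
    lexicographic gene order so downstream per-gene ranks are reproducible.
    """
    labelled = set(labels.sample_ids)

    def _keep_samples(x: ExpressionMatrix) -> ExpressionMatrix:
        keep = [s for s in x.sample_ids if s in labelled]
        if not keep:
            raise DataError(f"no labelled samples left on platform {x.platform!r}")
        return x.subset_samples(keep)

    a, b = _keep_samples(raw_a), _keep_samples(raw_b)
    shared = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not shared:
        raise DataError("no genes shared between the two platforms")
    a, b = a.subset_genes(shared), b.subset_genes(shared)

    ok = ~(np.isnan(a.values).any(axis=1) | np.isnan(b.values).any(axis=1))
    kept = [g for g, f in zip(shared, ok) if f]
    if not kept:
        raise DataError("every shared gene has missing values")
    a, b = a.subset_genes(kept), b.subset_genes(kept)

    dropped = {
        "genes_unshared": (len(set(raw_a.gene_ids) | set(raw_b.gene_ids)) - len(shared)),
        "genes_missing_values": len(shared) - len(kept),
        "samples_unlabelled_a": raw_a.n_samples - a.n_samples,
        "samples_unlabelled_b": raw_b.n_samples - b.n_samples,
        "genes_kept": len(kept),
    }
    logger.info(
        "clean_and_match: kept %d genes (%d unshared, %d with missing values dropped); "
        "dropped %d/%d unlabelled samples on %s/%s",
        len(kept), dropped["genes_unshared"], dropped["genes_missing_values"],
        dropped["samples_unlabelled_a"], dropped["samples_unlabelled_b"],
        a.platform or "A", b.platform or "B",
    )
    return CleanedPair(a, b, labels, dropped)
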