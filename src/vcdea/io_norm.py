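"""Count/design table IO, log-CPM normalization and gene filtering.

Counts are stored genes-by-samples.  Values may be non-integer: pseudo-count
quantifications (salmon, kallisto) are accepted as-is.  The default
normalization is log2 counts-per-million with a 0.5 offset in the numerator
and twice the offset added to the library size, which keeps zero counts
finite and is scale-invariant in the library size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "Design",
    "read_counts",
    "write_counts",
    "read_design",
    "log_cpm",
    "filter_genes",
]


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class CountMatrix:
    """Raw gene x sample counts with identifiers.

    Parameters
    ----------
    values : (G, n) array of non-negative, finite reals.
    gene_ids : G unique gene identifiers.
    sample_ids : n unique sample identifiers.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-dimensional")
        g, n = self.values.shape
        if g < 1 or n < 2:
            raise ValueError(f"need at least 1 gene and 2 samples, got {g} x {n}")
        if len(self.gene_ids) != g or len(self.sample_ids) != n:
            raise ValueError("id lists do not match matrix dimensions")
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.sample_ids, "sample_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("counts must be finite")
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class NormalizedMatrix:
    """Normalized expression matrix (same shape/ids as its source counts)."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    transform_tag: str = "identity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids do not match matrix rows")
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError("sample_ids do not match matrix columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized values must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class Design:
    """Per-sample design: nuisance covariates X and variables of interest Phi.

    ``X`` has shape (n, p) with p >= 0 (an intercept is always added
    internally and must not be included here); ``Phi`` has shape (n, k) with
    k >= 1 and holds the tested variables.
    """

    X: np.ndarray
    Phi: np.ndarray
    sample_ids: list[str]
    x_names: list[str] = field(default_factory=list)
    phi_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Phi = np.asarray(self.Phi, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.Phi.ndim == 1:
            self.Phi = self.Phi[:, None]
        n = len(self.sample_ids)
        if self.X.size == 0:
            self.X = np.empty((n, 0))
        if self.X.shape[0] != n or self.Phi.shape[0] != n:
            raise ValueError("X/Phi row counts do not match sample_ids")
        if self.Phi.shape[1] < 1:
            raise ValueError("Phi needs at least one column")
        if not self.x_names:
            self.x_names = [f"x{j}" for j in range(self.X.shape[1])]
        if not self.phi_names:
            self.phi_names = [f"phi{j}" for j in range(self.Phi.shape[1])]
        for j in range(self.Phi.shape[1]):
            if np.ptp(self.Phi[:, j]) == 0:
                raise ValueError(
                    f"variable of interest {self.phi_names[j]!r} is constant"
                )
        full = np.column_stack([np.ones(n), self.X, self.Phi])
        if np.linalg.matrix_rank(full) < full.shape[1]:
            raise ValueError("intercept + X + Phi is rank deficient")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def null_design(self) -> np.ndarray:
        """Intercept plus nuisance covariates, the design under H0."""
        return np.column_stack([np.ones(self.n_samples), self.X])

    def reordered(self, sample_ids: list[str]) -> "Design":
        """Return a copy with rows aligned to ``sample_ids``."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValueError(f"samples absent from design: {missing}")
        idx = [pos[s] for s in sample_ids]
        return Design(
            X=self.X[idx],
            Phi=self.Phi[idx],
            sample_ids=list(sample_ids),
            x_names=list(self.x_names),
            phi_names=list(self.phi_names),
        )


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=delimiter, dtype=str)


def read_counts(path: str | Path, delimiter: str | None = None) -> CountMatrix:
    """Read a counts table (first column gene ids, header sample ids).

    Input ordering of genes and samples is preserved.  Malformed numeric
    cells raise a parse error naming the offending gene and sample.
    """
    df = _read_table(path, delimiter)
    if df.shape[1] < 3:
        raise ValueError("counts table needs a gene-id column and >=2 samples")
    gene_ids = df.iloc[:, 0].tolist()
    sample_ids = df.columns[1:].tolist()
    raw = df.iloc[:, 1:]
    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.any(np.isnan(values)):
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"cannot parse count {raw.iat[i, j]!r} for gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    return CountMatrix(values=values, gene_ids=gene_ids, sample_ids=sample_ids)


def write_counts(counts: CountMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write a CountMatrix as TSV/CSV with full precision."""
    df = counts.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def read_design(
    path: str | Path,
    interest_columns: list[str],
    counts: CountMatrix | None = None,
    delimiter: str | None = None,
    sample_column: str = "sample_id",
) -> Design:
    """Read a design table: ``interest_columns`` become Phi, remaining
    numeric columns become X.  When ``counts`` is given, rows are realigned
    to its sample order (sample order is always owned by the count matrix).
    """
    df = _read_table(path, delimiter)
    if sample_column not in df.columns:
        raise ValueError(f"design table lacks a {sample_column!r} column")
    missing = [c for c in interest_columns if c not in df.columns]
    if missing:
        raise ValueError(f"interest columns not found in design: {missing}")
    sample_ids = df[sample_column].tolist()
    _check_unique(sample_ids, "design sample_ids")

    phi = df[interest_columns].apply(pd.to_numeric, errors="raise")
    x_cols = []
    for c in df.columns:
        if c == sample_column or c in interest_columns:
            continue
        col = pd.to_numeric(df[c], errors="coerce")
        if col.notna().all():
            x_cols.append(c)
        else:
            logger.warning("ignoring non-numeric design column %r", c)
    X = (
        df[x_cols].apply(pd.to_numeric).to_numpy(dtype=float)
        if x_cols
        else np.empty((len(sample_ids), 0))
    )
    design = Design(
        X=X,
        Phi=phi.to_numpy(dtype=float),
        sample_ids=sample_ids,
        x_names=x_cols,
        phi_names=list(interest_columns),
    )
    if counts is not None:
        extra = [s for s in counts.sample_ids if s not in set(sample_ids)]
        if extra:
            raise ValueError(f"count samples missing from design: {extra}")
        design = design.reordered(counts.sample_ids)
    return design


def log_cpm(
    counts: CountMatrix,
    lib_sizes: np.ndarray | None = None,
    prior_count: float = 0.5,
) -> NormalizedMatrix:
    """log2 counts-per-million.

    y_ig = log2( (r_ig + p_i) / (L_i + 2 * p_i) * 1e6 )

    with L_i the library size (column sum by default) and offset
    p_i = prior_count * L_i / 1e6 — i.e. ``prior_count`` is expressed in
    counts-per-million, so the transform equals log2(CPM + prior_count) up
    to a vanishing constant.  This keeps zero counts finite, is exactly
    invariant to joint rescaling of counts and library sizes, and reduces
    to a flat ``prior_count`` offset when L_i = 1e6.
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    if lib_sizes is None:
        lib_sizes = counts.values.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if lib_sizes.shape != (counts.n_samples,):
        raise ValueError("lib_sizes length does not match sample count")
    if np.any(lib_sizes <= 0):
        bad = counts.sample_ids[int(np.argmax(lib_sizes <= 0))]
        raise ValueError(f"non-positive library size for sample {bad!r}")
    prior = prior_count * lib_sizes / 1e6
    y = np.log2((counts.values + prior) / (lib_sizes + 2.0 * prior) * 1e6)
    return NormalizedMatrix(
        values=y,
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        transform_tag=f"log2-cpm(prior={prior_count})",
    )


def filter_genes(counts: CountMatrix, min_total: float = 0.0) -> CountMatrix:
    """Keep genes whose total count across samples is >= ``min_total``.

    Preserves input gene order; raises when no gene survives.
    """
    if min_total < 0:
        raise ValueError("min_total must be non-negative")
    totals = counts.values.sum(axis=1)
    keep = totals >= min_total
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(
            f"min_total={min_total} removed all {counts.n_genes} genes; "
            "lower the threshold"
        )
    if n_removed:
        logger.info("filter_genes removed %d/%d genes", n_removed, counts.n_genes)
    return CountMatrix(
        values=counts.values[keep],
        gene_ids=[g for g, k in zip(counts.gene_ids, keep) if k],
        sample_ids=list(counts.sample_ids),
    )
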