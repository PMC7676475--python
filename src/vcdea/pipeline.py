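"""End-to-end differential expression analysis.

normalize -> pooled precision weights -> per-gene score test ->
Benjamini-Hochberg correction -> DE calls.  Results are returned as a
pandas DataFrame with one row per input gene (zero-variance genes are kept
with NA statistics, never silently dropped).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_norm import CountMatrix, Design, NormalizedMatrix, log_cpm
from .weights import estimate_weights, fit_null_models
from .score_test import batch_asymptotic, batch_permutation

logger = logging.getLogger(__name__)

__all__ = ["bh_adjust", "log2_fold_change", "run_dea", "call_de_genes"]

RESULT_COLUMNS = ["gene_id", "Q", "pvalue", "padj", "log2fc", "method", "n_perm"]


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, compute p * G / rank, take the running minimum from the
    largest rank down, cap at 1, and return in the original order.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    G = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * G / np.arange(1, G + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(G)
    out[order] = adj
    return out


def log2_fold_change(y: NormalizedMatrix, group: np.ndarray) -> np.ndarray:
    """Per-gene difference of mean normalized expression, group 1 minus
    group 0.  ``group`` is a binary indicator over samples."""
    group = np.asarray(group).ravel()
    if group.size != y.n_samples:
        raise ValueError("group length does not match sample count")
    g1 = group == np.max(group)
    g0 = ~g1
    if not g0.any() or not g1.any():
        raise ValueError("both groups must be non-empty")
    return y.values[:, g1].mean(axis=1) - y.values[:, g0].mean(axis=1)


def _two_group_indicator(design: Design) -> np.ndarray | None:
    """The single Phi column when it encodes two groups, else None."""
    if design.Phi.shape[1] != 1:
        return None
    col = design.Phi[:, 0]
    if np.unique(col).size != 2:
        return None
    return (col == col.max()).astype(float)


def run_dea(
    counts: CountMatrix | NormalizedMatrix,
    design: Design,
    test: str = "asymptotic",
    n_perm: int = 1000,
    seed: int = 0,
    preprocessed: bool = False,
    bandwidth: float | None = None,
) -> pd.DataFrame:
    """Run the full analysis and return the per-gene result table.

    Parameters
    ----------
    counts : raw counts, or already-normalized expression if
        ``preprocessed`` is set (then no log-CPM transform is applied).
        Passing a :class:`NormalizedMatrix` implies ``preprocessed``.
    design : sample design aligned to ``counts``; alignment is enforced.
    test : "asymptotic" or "permutation".
    n_perm, seed : permutation count and RNG seed (permutation test only;
        the seed also fixes any weight-smoother subsampling).

    Deterministic given (inputs, test, n_perm, seed).
    """
    if test not in ("asymptotic", "permutation"):
        raise ValueError(f"unknown test {test!r}")
    if design.sample_ids != counts.sample_ids:
        design = design.reordered(counts.sample_ids)

    if isinstance(counts, NormalizedMatrix):
        y = counts
    elif preprocessed:
        y = NormalizedMatrix(
            values=counts.values,
            gene_ids=list(counts.gene_ids),
            sample_ids=list(counts.sample_ids),
            transform_tag="preprocessed",
        )
    else:
        y = log_cpm(counts)

    variable = np.ptp(y.values, axis=1) > 0
    n_skipped = int((~variable).sum())
    if n_skipped:
        logger.warning("%d zero-variance genes skipped (NA rows)", n_skipped)

    y_used = NormalizedMatrix(
        values=y.values[variable],
        gene_ids=[g for g, v in zip(y.gene_ids, variable) if v],
        sample_ids=list(y.sample_ids),
        transform_tag=y.transform_tag,
    )
    if y_used.n_genes == 0:
        raise ValueError("no gene with nonzero variance")

    null_fit = fit_null_models(y_used, design)
    pw = estimate_weights(
        y_used, design, bandwidth=bandwidth, null_fit=null_fit, subsample_seed=seed
    )

    if test == "asymptotic":
        Q, pvals = batch_asymptotic(null_fit, pw.sigma, design.Phi)
        n_perm_used = None
    else:
        Q, pvals = batch_permutation(
            null_fit,
            pw.sigma,
            design.Phi,
            has_covariates=design.X.shape[1] > 0,
            n_perm=n_perm,
            seed=seed,
        )
        n_perm_used = n_perm

    padj = bh_adjust(np.clip(pvals, 1e-300, 1.0))

    group = _two_group_indicator(design)
    lfc_used = log2_fold_change(y_used, group) if group is not None else None

    G = counts.n_genes
    table = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "Q": np.full(G, np.nan),
            "pvalue": np.full(G, np.nan),
            "padj": np.full(G, np.nan),
            "log2fc": np.full(G, np.nan),
            "method": test,
            "n_perm": n_perm_used if n_perm_used is not None else pd.NA,
        }
    )
    idx = np.flatnonzero(variable)
    table.loc[idx, "Q"] = Q
    table.loc[idx, "pvalue"] = pvals
    table.loc[idx, "padj"] = padj
    if lfc_used is not None:
        table.loc[idx, "log2fc"] = lfc_used
    return table


def call_de_genes(
    table: pd.DataFrame, alpha: float = 0.05, lfc_threshold: float = 0.0
) -> set[str]:
    """Genes with adjusted p < alpha and |log2FC| > lfc_threshold.

    Both inequalities are strict.  When ``lfc_threshold`` is 0 only the
    adjusted p-value criterion applies (any finite fold change passes).
    """
    if "padj" not in table.columns:
        raise ValueError("table lacks adjusted p-values")
    sig = table["padj"] < alpha
    if lfc_threshold > 0:
        if table["log2fc"].isna().all():
            raise ValueError("lfc_threshold > 0 but table has no fold changes")
        sig &= table["log2fc"].abs() > lfc_threshold
    return set(table.loc[sig.fillna(False), "gene_id"])
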