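"""Error-rate benchmarking over Monte-Carlo replicates and gene-level
predictive diagnostics.

Per replicate: type I error is the fraction of true-null genes with raw
p below alpha; the false discovery proportion (FDP) is the fraction of
BH-declared genes that are truly null (0 when nothing is declared); power
and the true discovery proportion are their complements on the true-DE
side.  Replicate seeds are spawned from the master seed so each replicate
is independent and individually reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import chi2

from .pipeline import run_dea
from .simulate import SimConfig, SimDataset, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorMetrics",
    "confusion_metrics",
    "monte_carlo_benchmark",
    "loo_brier_score",
    "marginal_logistic_pvalue",
]


@dataclass
class ErrorMetrics:
    """Monte-Carlo means and standard errors of the four error metrics."""

    type1: float
    fdr: float
    power: float | None
    tdr: float | None
    n_reps: int
    mc_se: dict[str, float]
    any_discovery: float | None = None

    def to_frame(self):
        import pandas as pd

        rows = []
        for name in ("type1", "fdr", "power", "tdr", "any_discovery"):
            val = getattr(self, name)
            if val is None:
                continue
            rows.append(
                {
                    "metric": name,
                    "estimate": val,
                    "mc_se": self.mc_se.get(name, np.nan),
                    "n_reps": self.n_reps,
                }
            )
        return pd.DataFrame(rows)


def confusion_metrics(
    raw_p: np.ndarray,
    padj: np.ndarray,
    truth: np.ndarray,
    alpha: float = 0.05,
) -> dict[str, float | None]:
    """Single-replicate error metrics from aligned p-value/truth vectors.

    Returns type1, power (None when no true DE gene), fdp (0 when no
    discoveries), tdp (None when no discoveries), and the any-discovery
    indicator used for null-only family-wise summaries.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    raw_p = np.asarray(raw_p, dtype=float).ravel()
    padj = np.asarray(padj, dtype=float).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if not (raw_p.size == padj.size == truth.size):
        raise ValueError("metric inputs must be aligned")

    null = ~truth
    type1 = float(np.mean(raw_p[null] < alpha)) if null.any() else None
    power = float(np.mean(raw_p[truth] < alpha)) if truth.any() else None
    declared = padj < alpha
    n_declared = int(declared.sum())
    if n_declared:
        fdp = float(np.mean(null[declared]))
        tdp = 1.0 - fdp
    else:
        fdp, tdp = 0.0, None
    return {
        "type1": type1,
        "power": power,
        "fdp": fdp,
        "tdp": tdp,
        "any_discovery": float(n_declared > 0),
    }


def _mean_se(values: list[float]) -> tuple[float | None, float]:
    vals = [v for v in values if v is not None]
    if not vals:
        return None, np.nan
    arr = np.asarray(vals, dtype=float)
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else np.nan
    return float(arr.mean()), se


def monte_carlo_benchmark(
    scenario_config: SimConfig,
    test: str = "asymptotic",
    n_reps: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    n_perm: int = 500,
    progress: bool = False,
) -> ErrorMetrics:
    """Simulate -> analyze -> score, ``n_reps`` times, and aggregate.

    Replicate seeds come from ``numpy.random.SeedSequence(seed).spawn``,
    a counter-based scheme: replicate j is reproducible in isolation.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    child_seeds = np.random.SeedSequence(seed).spawn(n_reps)
    per_rep: dict[str, list] = {
        k: [] for k in ("type1", "power", "fdp", "tdp", "any_discovery")
    }
    for j, ss in enumerate(child_seeds):
        rep_seed = int(ss.generate_state(1)[0])
        dataset: SimDataset = simulate(scenario_config, seed=rep_seed)
        table = run_dea(
            dataset.counts,
            dataset.design,
            test=test,
            n_perm=n_perm,
            seed=rep_seed,
        )
        ok = table["pvalue"].notna().to_numpy()
        metrics = confusion_metrics(
            table["pvalue"].to_numpy()[ok],
            table["padj"].to_numpy()[ok],
            dataset.truth[ok],
            alpha=alpha,
        )
        for k, v in metrics.items():
            per_rep[k].append(v)
        if progress and (j + 1) % 10 == 0:
            logger.info("benchmark replicate %d/%d done", j + 1, n_reps)

    mc_se: dict[str, float] = {}
    type1, mc_se["type1"] = _mean_se(per_rep["type1"])
    fdr, mc_se["fdr"] = _mean_se(per_rep["fdp"])
    power, mc_se["power"] = _mean_se(per_rep["power"])
    tdr, mc_se["tdr"] = _mean_se(per_rep["tdp"])
    any_disc, mc_se["any_discovery"] = _mean_se(per_rep["any_discovery"])
    return ErrorMetrics(
        type1=type1,
        fdr=fdr,
        power=power,
        tdr=tdr,
        n_reps=n_reps,
        mc_se=mc_se,
        any_discovery=any_disc,
    )


def _clip_prob(p: np.ndarray) -> np.ndarray:
    return np.clip(p, 1e-8, 1.0 - 1e-8)


def _fit_logistic(x: np.ndarray, labels: np.ndarray):
    X = sm.add_constant(x, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(labels, X, family=sm.families.Binomial())
        return model.fit(maxiter=200)


def loo_brier_score(x_g: np.ndarray, labels: np.ndarray) -> float:
    """Leave-one-out cross-validated Brier score of a univariate logistic
    classifier: BS = (1/n) * sum_i (pi_hat_{-i}(x_i) - label_i)^2.

    Predictions from (quasi-)separable folds are clipped into
    [1e-8, 1 - 1e-8].
    """
    x_g = np.asarray(x_g, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    n = x_g.size
    if labels.size != n:
        raise ValueError("x and labels must be aligned")
    if n < 3:
        raise ValueError("need n >= 3 for leave-one-out")
    if np.unique(labels).size != 2:
        raise ValueError("labels must contain both classes")
    labels = (labels == labels.max()).astype(float)

    sq_err = np.empty(n)
    warned = False
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_tr, x_tr = labels[mask], x_g[mask]
        if np.unique(y_tr).size < 2:
            pred = float(y_tr.mean())
        else:
            try:
                res = _fit_logistic(x_tr, y_tr)
                pred = float(
                    res.predict(sm.add_constant(np.array([[x_g[i]]]), has_constant="add"))[0]
                )
                if not np.isfinite(pred):
                    raise ValueError
            except Exception:
                pred = float(y_tr.mean())
            if pred < 1e-8 or pred > 1 - 1e-8:
                warned = True
        pred = float(_clip_prob(np.array([pred]))[0])
        sq_err[i] = (pred - labels[i]) ** 2
    if warned:
        logger.warning("separable leave-one-out folds: predictions clipped")
    return float(sq_err.mean())


def marginal_logistic_pvalue(x_g: np.ndarray, labels: np.ndarray) -> float | None:
    """Two-sided likelihood-ratio p-value for the slope of a univariate
    logistic regression of ``labels`` on ``x_g``.

    Returns None on non-convergence.  Invariant to affine rescaling of x;
    exactly 1 when x carries no information (zero deviance reduction).
    """
    x_g = np.asarray(x_g, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    if labels.size != x_g.size:
        raise ValueError("x and labels must be aligned")
    if np.unique(labels).size != 2:
        raise ValueError("labels must contain both classes")
    labels = (labels == labels.max()).astype(float)
    if np.ptp(x_g) == 0:
        return 1.0
    try:
        full = _fit_logistic(x_g, labels)
        null = sm.GLM(
            labels, np.ones((labels.size, 1)), family=sm.families.Binomial()
        ).fit()
        lr = 2.0 * (full.llf - null.llf)
    except Exception:
        logger.warning("logistic regression failed to converge; p-value absent")
        return None
    if not np.isfinite(lr):
        return None
    return float(chi2.sf(max(lr, 0.0), df=1))
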