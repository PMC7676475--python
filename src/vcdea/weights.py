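"""Per-observation standard-deviation estimates from a pooled mean-variance fit.

Each gene is first fitted by OLS under the null (intercept + nuisance
covariates only).  The (fitted mean, squared residual) pairs of all genes
are then pooled and a local linear regression of the log squared residual
on the fitted mean estimates a shared variance trend, in the spirit of
precision-weight approaches for count data.  Because
E[log(eps^2)] = log(sigma^2) - (log 2 + gamma) for Gaussian errors, the
exponentiated fit is multiplied by exp(log 2 + gamma) so the estimator is
unbiased for sigma^2 on homoscedastic Gaussian data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_norm import Design, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NullFit",
    "PrecisionWeights",
    "fit_null_models",
    "local_linear_regression",
    "estimate_weights",
]

# E[log chi2_1] = -(log 2 + Euler-Mascheroni); used to debias the log proxy.
_LOG_CHI2_1_MEAN = -(np.log(2.0) + np.euler_gamma)


@dataclass
class NullFit:
    """Gene-wise OLS fits under the null design (intercept + X)."""

    coefficients: np.ndarray  # (G, p+1)
    mu: np.ndarray  # (G, n) fitted means
    residuals: np.ndarray  # (G, n)
    null_design: np.ndarray  # (n, p+1)


@dataclass
class PrecisionWeights:
    """Per-observation standard deviations sigma_ig (all >= floor > 0)."""

    sigma: np.ndarray  # (G, n)
    bandwidth: float
    floor: float

    def __post_init__(self) -> None:
        if self.floor <= 0:
            raise ValueError("floor must be positive")
        if not np.all(np.isfinite(self.sigma)):
            raise ValueError("sigma must be finite")
        if np.any(self.sigma < self.floor):
            raise ValueError("sigma entries below the floor")


def fit_null_models(y: NormalizedMatrix, design: Design) -> NullFit:
    """OLS of each gene's expression on the null design (Phi excluded).

    Requires n > p + 1.  Residuals are exactly orthogonal to the null
    design columns, so they sum to zero per gene.
    """
    D = design.null_design()
    n, q = D.shape
    if y.n_samples != n:
        raise ValueError("expression and design sample counts differ")
    if np.linalg.matrix_rank(D) < q:
        raise ValueError("null design (intercept + X) is rank deficient")
    if n <= q:
        raise ValueError(f"need n > p + 1 (n={n}, p+1={q})")
    # shared design across genes: one pseudo-inverse, applied to all rows
    pinv = np.linalg.pinv(D)  # (q, n)
    coef = y.values @ pinv.T  # (G, q)
    mu = coef @ D.T
    resid = y.values - mu
    return NullFit(coefficients=coef, mu=mu, residuals=resid, null_design=D)


def local_linear_regression(
    x: np.ndarray,
    y: np.ndarray,
    eval_points: np.ndarray,
    bandwidth: float,
) -> np.ndarray:
    """Gaussian-kernel local linear regression evaluated at ``eval_points``.

    At each evaluation point t a weighted least-squares line is fitted with
    kernel weights exp(-((x - t) / h)^2 / 2) and the local intercept is
    returned.  Degenerate neighbourhoods (all weights underflow) fall back
    to the nearest data value.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    eval_points = np.asarray(eval_points, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 2:
        raise ValueError("need at least 2 data points")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    out = np.empty(eval_points.size)
    for j, t in enumerate(eval_points):
        z = (x - t) / bandwidth
        w = np.exp(-0.5 * np.minimum(z * z, 1400.0))
        sw = w.sum()
        if sw <= 1e-290:
            nearest = int(np.argmin(np.abs(x - t)))
            logger.debug("degenerate neighbourhood at %g; nearest-value fallback", t)
            out[j] = y[nearest]
            continue
        d = x - t
        s0, s1, s2 = sw, (w * d).sum(), (w * d * d).sum()
        b0, b1 = (w * y).sum(), (w * d * y).sum()
        det = s0 * s2 - s1 * s1
        if det <= 1e-12 * max(s0 * s2, 1e-300):
            out[j] = b0 / s0  # collinear neighbourhood: local constant fit
        else:
            out[j] = (s2 * b0 - s1 * b1) / det
    return out


def _silverman_bandwidth(x: np.ndarray) -> float:
    """Rule-of-thumb bandwidth on the pooled fitted means."""
    sd = float(np.std(x))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        scale = max(abs(float(np.mean(x))), 1.0)
    return 0.9 * scale * x.size ** (-0.2)


def estimate_weights(
    y: NormalizedMatrix,
    design: Design,
    bandwidth: float | None = None,
    floor: float | None = None,
    null_fit: NullFit | None = None,
    n_grid: int = 256,
    max_fit_points: int = 5_000_000,
    subsample_seed: int = 0,
) -> PrecisionWeights:
    """Estimate sigma_ig by pooling all genes' (mean, residual) pairs.

    log(residual^2 + 1e-8) is smoothed against the fitted mean with
    :func:`local_linear_regression` on a grid spanning the pooled means,
    then evaluated everywhere by linear interpolation (exact at the grid;
    the grid is dense relative to the bandwidth).  The exponentiated fit is
    debiased by exp(log 2 + gamma) and floored.
    """
    if null_fit is None:
        null_fit = fit_null_models(y, design)
    mu = null_fit.mu.ravel()
    resid = null_fit.residuals.ravel()
    if np.allclose(resid, 0.0):
        raise ValueError("all residuals are zero; cannot estimate a variance trend")
    proxy = np.log(resid * resid + 1e-8)

    if bandwidth is None:
        bandwidth = _silverman_bandwidth(mu)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    fit_mu, fit_proxy = mu, proxy
    if mu.size > max_fit_points:
        rng = np.random.default_rng(subsample_seed)
        idx = rng.choice(mu.size, size=max_fit_points, replace=False)
        fit_mu, fit_proxy = mu[idx], proxy[idx]
        logger.info("smoother fitted on a %d-point subsample", max_fit_points)

    lo, hi = float(mu.min()), float(mu.max())
    if lo == hi:
        grid = np.array([lo, lo + 1.0])
        smoothed_grid = np.full(2, float(np.mean(fit_proxy)))
    else:
        grid = np.linspace(lo, hi, n_grid)
        smoothed_grid = local_linear_regression(fit_mu, fit_proxy, grid, bandwidth)
    smoothed = np.interp(mu, grid, smoothed_grid)

    var = np.exp(smoothed - _LOG_CHI2_1_MEAN)
    sigma_raw = np.sqrt(var)
    if floor is None:
        floor = max(1e-4 * float(np.median(sigma_raw)), 1e-12)
    sigma = np.maximum(sigma_raw, floor).reshape(null_fit.mu.shape)
    return PrecisionWeights(sigma=sigma, bandwidth=float(bandwidth), floor=float(floor))
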