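"""Gene-wise variance component score test.

For one gene with normalized expression y, null-model mean mu and
per-observation standard deviations sigma, the score vector is

    q = n^{-1/2} sum_i (y_i - mu_i) / sigma_i * Phi_i          (k-vector)

and the statistic is Q = q'q.  Under the null, Q is asymptotically a
nonnegative mixture sum_l a_l chi2_1 whose coefficients a_l are the
eigenvalues of the covariance of the per-sample contribution rows
(y_i - mu_i)/sigma_i * Phi_i, estimated after projecting the contributions
off the null design to account for nuisance-parameter estimation.  Tail
probabilities use characteristic-function inversion (Imhof) with a
moment-matching fallback (Liu); small samples can use a permutation test
on the same statistic with the (b+1)/(m+1) p-value estimator, which is
never zero and remains valid under random permutations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import chi2, ncx2

from .io_norm import Design
from .weights import fit_null_models, NullFit

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreResult",
    "score_statistic",
    "score_contributions",
    "mixture_coefficients",
    "chi2_mixture_pvalue",
    "asymptotic_test",
    "phipson_smyth_pvalue",
    "permutation_test",
]

_PMIN = 1e-300


@dataclass
class ScoreResult:
    """Outcome of a single-gene score test."""

    q: np.ndarray
    Q: float
    a: np.ndarray | None
    pvalue: float
    method: str
    n_perm_used: int | None = None


def _check_inputs(y_g, mu_g, sigma_g, Phi):
    y_g = np.asarray(y_g, dtype=float).ravel()
    mu_g = np.asarray(mu_g, dtype=float).ravel()
    sigma_g = np.asarray(sigma_g, dtype=float).ravel()
    Phi = np.asarray(Phi, dtype=float)
    if Phi.ndim == 1:
        Phi = Phi[:, None]
    n = y_g.size
    if mu_g.size != n or sigma_g.size != n or Phi.shape[0] != n:
        raise ValueError("y, mu, sigma and Phi must share the sample dimension")
    if np.any(sigma_g <= 0):
        raise ValueError("all sigma must be strictly positive")
    return y_g, mu_g, sigma_g, Phi


def score_statistic(y_g, mu_g, sigma_g, Phi) -> tuple[np.ndarray, float]:
    """Score vector q and statistic Q = q'q for one gene."""
    y_g, mu_g, sigma_g, Phi = _check_inputs(y_g, mu_g, sigma_g, Phi)
    n = y_g.size
    s = (y_g - mu_g) / sigma_g
    # summed as the contribution rows so both routes agree bit-for-bit
    q = (s[:, None] * Phi).sum(axis=0) / np.sqrt(n)
    return q, float(q @ q)


def score_contributions(y_g, mu_g, sigma_g, Phi) -> np.ndarray:
    """Per-sample contribution rows (y_i - mu_i)/sigma_i * Phi_i, shape (n, k).

    Column sums scaled by n^{-1/2} reproduce the score vector exactly.
    """
    y_g, mu_g, sigma_g, Phi = _check_inputs(y_g, mu_g, sigma_g, Phi)
    s = (y_g - mu_g) / sigma_g
    return s[:, None] * Phi


def mixture_coefficients(
    contributions: np.ndarray, null_projection: np.ndarray
) -> np.ndarray:
    """Eigenvalues of the covariance of the contribution rows.

    Contributions are projected off the column space of the null design
    (which includes the intercept, hence also centers them) before the
    covariance is formed with denominator n - 1.  The covariance is then
    scaled by nu / (nu - 2), nu = n - rank(null design): the tail uses
    1 / a, whose plug-in is biased by (nu - 2) / nu for a chi-square-type
    variance estimate, and the correction removes the resulting size
    inflation.  Negative eigenvalue estimates are clipped to zero.
    """
    C = np.asarray(contributions, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    D = np.asarray(null_projection, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    n, k = C.shape
    if n <= 1:
        raise ValueError("need n > 1 to estimate mixture coefficients")
    C_perp = C - D @ np.linalg.lstsq(D, C, rcond=None)[0]
    cov = (C_perp.T @ C_perp) / (n - 1)
    nu = n - np.linalg.matrix_rank(D)
    if nu > 2:
        cov = cov * (nu / (nu - 2.0))
    if n <= k:
        warnings.warn(
            f"n={n} <= k={k}: mixture covariance regularized", stacklevel=2
        )
        cov = cov + np.eye(k) * (np.trace(cov) / k + 1e-12) * 1e-6
    a = np.linalg.eigvalsh(cov)
    neg = a < 0
    if np.any(a < -1e-10 * max(a.max(initial=0.0), 1.0)):
        logger.debug("clipped negative eigenvalue estimates: %s", a[neg])
    return np.clip(a, 0.0, None)[::-1].copy()


def _liu_pvalue(Q: float, a: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matching approximation to P(sum a_l chi2_1 > Q)."""
    c1 = a.sum()
    c2 = (a**2).sum()
    c3 = (a**3).sum()
    c4 = (a**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        t = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * t**3 - t**2
        df = t**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    mu_x = df + delta
    sigma_x = np.sqrt(2.0) * np.sqrt(df + 2 * delta)
    t_star = (Q - c1) / np.sqrt(2 * c2)
    x = t_star * sigma_x + mu_x
    return float(ncx2.sf(x, df, delta)) if delta > 0 else float(chi2.sf(x, df))


def chi2_mixture_pvalue(Q: float, a: np.ndarray, accuracy: float = 1e-9) -> float:
    """P(sum_l a_l chi2_1 > Q) for nonnegative coefficients a.

    Exact characteristic-function inversion (Imhof) with a Liu
    moment-matching fallback on numerical failure; degenerate cases with
    equal coefficients collapse to closed-form chi-square tails.
    """
    Q = float(Q)
    if Q < 0:
        raise ValueError("Q must be non-negative")
    a = np.asarray(a, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("mixture coefficients must be non-empty")
    if np.any(a < 0):
        raise ValueError("mixture coefficients must be non-negative")
    a = a[a > 0]
    if a.size == 0:
        if Q > 0:
            warnings.warn("all mixture coefficients are zero with Q > 0", stacklevel=2)
            return 0.0
        return 1.0
    if Q == 0.0:
        return 1.0
    # equal coefficients: a * chi2_L exactly
    if np.allclose(a, a[0], rtol=1e-12, atol=0.0):
        return float(np.clip(chi2.sf(Q / a[0], df=a.size), _PMIN, 1.0))

    # Imhof inversion: p = 1/2 + (1/pi) * Int_0^inf sin(theta(u))/(u rho(u)) du
    # with theta = phi(u) - omega*u, phi = sum(arctan(a u))/2, omega = Q/2.
    # The integrand oscillates at frequency omega forever, so the tail
    # [1, inf) is handled with QUADPACK's Fourier-weighted rules after
    # expanding sin(phi - omega u) = sin(phi)cos(omega u) - cos(phi)sin(omega u).
    omega = 0.5 * Q

    def _phi(u):
        return 0.5 * np.arctan(a * u).sum()

    def _inv_urho(u):
        return np.exp(-0.25 * np.log1p((a * u) ** 2).sum()) / u

    def head(u):  # bounded as u -> 0: sin(theta) ~ (sum(a)/2 - omega) u
        if u == 0.0:
            return 0.5 * a.sum() - omega
        return np.sin(_phi(u) - omega * u) * _inv_urho(u)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", integrate.IntegrationWarning)
            head_val, head_err = integrate.quad(
                head, 0.0, 1.0, epsabs=accuracy, limit=200
            )
            cos_val, cos_err = integrate.quad(
                lambda u: np.sin(_phi(u)) * _inv_urho(u),
                1.0,
                np.inf,
                weight="cos",
                wvar=omega,
                limlst=200,
            )
            sin_val, sin_err = integrate.quad(
                lambda u: np.cos(_phi(u)) * _inv_urho(u),
                1.0,
                np.inf,
                weight="sin",
                wvar=omega,
                limlst=200,
            )
        val = head_val + cos_val - sin_val
        p = 0.5 + val / np.pi
        if not np.isfinite(p) or (head_err + cos_err + sin_err) > 1e-6:
            raise RuntimeError("inversion did not converge")
    except Exception:  # fall back to moment matching
        logger.debug("Imhof inversion failed for Q=%g; using Liu fallback", Q)
        p = _liu_pvalue(Q, a)
    return float(np.clip(p, _PMIN, 1.0))


def _single_gene_null_fit(y_g: np.ndarray, design: Design) -> tuple[np.ndarray, np.ndarray]:
    D = design.null_design()
    coef, *_ = np.linalg.lstsq(D, np.asarray(y_g, dtype=float), rcond=None)
    mu = D @ coef
    return mu, D


def _null_hat_pieces(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residual-maker matrix M = I - D D^+ and hat-diagonal of the null fit."""
    pinv = np.linalg.pinv(D)
    n = D.shape[0]
    M = np.eye(n) - D @ pinv
    h = np.einsum("ij,ji->i", D, pinv)
    return M, h


def _adjusted_contributions(
    resid: np.ndarray, sigma: np.ndarray, Phi: np.ndarray, M: np.ndarray, h: np.ndarray
) -> np.ndarray:
    """Per-sample score contributions with nuisance estimation accounted for.

    Writing the score as q = n^{-1/2} sum_i eps_i * psi_i with
    psi = M (Phi / sigma) (M the null residual-maker), the covariance of
    q is estimated from rows eps_hat_i * psi_i, where eps_hat are
    leverage-corrected residuals resid / sqrt(1 - h_ii).  Projecting the
    weighted design — rather than the raw contribution rows — off the null
    space is what keeps the null distribution calibrated.
    """
    eps_hat = resid / np.sqrt(np.clip(1.0 - h, 1e-10, 1.0))
    psi = M @ (Phi / sigma[:, None])
    return eps_hat[:, None] * psi


def asymptotic_test(y_g, design: Design, sigma_g) -> ScoreResult:
    """Asymptotic mixture-of-chi-square score test for one gene.

    Deterministic: fits the null model, forms q and Q, estimates the
    mixture coefficients and inverts the tail probability.
    """
    y_g = np.asarray(y_g, dtype=float).ravel()
    sigma_g = np.asarray(sigma_g, dtype=float).ravel()
    mu, D = _single_gene_null_fit(y_g, design)
    q, Q = score_statistic(y_g, mu, sigma_g, design.Phi)
    M, h = _null_hat_pieces(D)
    C = _adjusted_contributions(y_g - mu, sigma_g, design.Phi, M, h)
    a = mixture_coefficients(C, D)
    p = chi2_mixture_pvalue(Q, a) if a.sum() > 0 else (1.0 if Q == 0 else 0.0)
    return ScoreResult(q=q, Q=Q, a=a, pvalue=p, method="asymptotic")


def phipson_smyth_pvalue(b: int, m: int) -> float:
    """Permutation p-value (b + 1) / (m + 1): never zero, valid under
    random (non-exhaustive) permutations."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if b < 0 or b > m:
        raise ValueError(f"b must lie in [0, m], got b={b}, m={m}")
    return (b + 1) / (m + 1)


def permutation_test(
    y_g,
    design: Design,
    sigma_g,
    n_perm: int = 1000,
    rng_seed: int | np.random.Generator = 0,
) -> ScoreResult:
    """Permutation test on the same statistic Q.

    Without nuisance covariates the rows of Phi are permuted.  With
    covariates a Freedman-Lane scheme is used: null-model residuals are
    permuted, pseudo-responses rebuilt and the null model refitted, so the
    covariate-response relation is preserved.  Weights are held fixed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y_g = np.asarray(y_g, dtype=float).ravel()
    sigma_g = np.asarray(sigma_g, dtype=float).ravel()
    mu, D = _single_gene_null_fit(y_g, design)
    q, Q_obs = score_statistic(y_g, mu, sigma_g, design.Phi)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n = y_g.size
    resid = y_g - mu
    s = resid / sigma_g
    has_covariates = design.X.shape[1] > 0
    if has_covariates:
        M = np.eye(n) - D @ np.linalg.pinv(D)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if has_covariates:
            r_star = M @ resid[perm]
            q_p = ((r_star / sigma_g) @ design.Phi) / np.sqrt(n)
        else:
            q_p = (s @ design.Phi[perm]) / np.sqrt(n)
        if float(q_p @ q_p) >= Q_obs:
            b += 1
    p = phipson_smyth_pvalue(b, n_perm)
    return ScoreResult(
        q=q, Q=Q_obs, a=None, pvalue=p, method="permutation", n_perm_used=n_perm
    )


# ---------------------------------------------------------------------------
# Vectorized batch paths used by the pipeline (same math as the per-gene API)
# ---------------------------------------------------------------------------


def batch_asymptotic(
    null_fit: NullFit, sigma: np.ndarray, Phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Asymptotic test for all genes at once; returns (Q, pvalues).

    k = 1 uses a fully vectorized closed form (single chi-square tail);
    k > 1 loops over genes with the shared projection precomputed.
    """
    resid = null_fit.residuals
    D = null_fit.null_design
    G, n = resid.shape
    if Phi.ndim == 1:
        Phi = Phi[:, None]
    k = Phi.shape[1]
    S = resid / sigma
    q = (S @ Phi) / np.sqrt(n)  # (G, k)
    Q = np.einsum("gk,gk->g", q, q)
    M, h = _null_hat_pieces(D)
    eps_hat = resid / np.sqrt(np.clip(1.0 - h, 1e-10, 1.0))[None, :]
    pvals = np.empty(G)
    if k == 1:
        psi = (Phi[:, 0][None, :] / sigma) @ M  # (G, n), M symmetric
        C = eps_hat * psi  # adjusted contribution rows per gene
        C_perp = C @ M  # the projection inside mixture_coefficients
        a = np.einsum("gn,gn->g", C_perp, C_perp) / (n - 1)
        nu = n - np.linalg.matrix_rank(D)
        if nu > 2:
            a = a * (nu / (nu - 2.0))
        a = np.clip(a, 0.0, None)
        ok = a > 0
        pvals[ok] = np.clip(chi2.sf(Q[ok] / a[ok], df=1), _PMIN, 1.0)
        pvals[~ok] = np.where(Q[~ok] > 0, 0.0, 1.0)
    else:
        for g in range(G):
            C = _adjusted_contributions(resid[g], sigma[g], Phi, M, h)
            a_g = mixture_coefficients(C, D)
            if a_g.sum() > 0:
                pvals[g] = chi2_mixture_pvalue(Q[g], a_g)
            else:
                pvals[g] = 1.0 if Q[g] == 0 else 0.0
    return Q, pvals


def batch_permutation(
    null_fit: NullFit,
    sigma: np.ndarray,
    Phi: np.ndarray,
    has_covariates: bool,
    n_perm: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation test for all genes sharing one seeded permutation set.

    Returns (Q, pvalues) with p = (b + 1) / (n_perm + 1) per gene.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    resid = null_fit.residuals
    D = null_fit.null_design
    G, n = resid.shape
    if Phi.ndim == 1:
        Phi = Phi[:, None]
    S = resid / sigma
    q = (S @ Phi) / np.sqrt(n)
    Q_obs = np.einsum("gk,gk->g", q, q)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    b = np.zeros(G, dtype=int)
    # statistics compared with a tiny relative tolerance so ties (e.g. the
    # identity permutation appearing by chance) count as >=
    tol = 1e-12 * np.maximum(Q_obs, 1.0)
    if has_covariates:
        M = np.eye(n) - D @ np.linalg.pinv(D)
        for perm in perms:
            r_star = resid[:, perm] @ M.T
            q_p = ((r_star / sigma) @ Phi) / np.sqrt(n)
            Q_p = np.einsum("gk,gk->g", q_p, q_p)
            b += Q_p >= Q_obs - tol
    else:
        for start in range(0, n_perm, 200):
            block = perms[start : start + 200]
            # (n, k*len(block)) matrix of permuted Phi columns
            P = Phi[block.T].reshape(n, -1)
            q_p = (S @ P) / np.sqrt(n)  # (G, len(block)*k)
            Q_p = (q_p**2).reshape(G, len(block), Phi.shape[1]).sum(axis=2)
            b += (Q_p >= (Q_obs - tol)[:, None]).sum(axis=1)
    pvals = (b + 1) / (n_perm + 1)
    return Q_obs, pvals
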