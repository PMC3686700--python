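"""Single-random-effect linear mixed model fitted by REML.

Model: y = X beta + a + e with a ~ N(0, K sigma_a^2), e ~ N(0, I sigma_e^2),
K a (pedigree or genomic) relationship matrix. The restricted likelihood is
profiled over delta = sigma_e^2 / sigma_a^2 after a one-time eigendecomposition
of S K S (S the projection orthogonal to the fixed effects), as in EMMA: a
coarse log-spaced grid bracketing, then bounded scalar refinement. Heritability
is h^2 = sigma_a^2 / (sigma_a^2 + sigma_e^2) = 1 / (1 + delta).

The reported log-likelihoods use the restricted-likelihood convention

    logRL = -1/2 [ (n-q) log 2pi + log|V| + log|X' V^-1 X| + r' V^-1 r ],

under which the intercept-only model has the closed form implemented in
``loglik_null``, so Eq.-style likelihood-ratio variance-explained statistics
(``r2_lr``) are internally consistent between the mixed and null fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .relatedness import KinshipMatrix

__all__ = ["REMLFit", "reml_fit", "loglik_null", "r2_lr", "restricted_loglik"]

_DELTA_BOUNDS = (1e-5, 1e5)
_GRID_POINTS = 100


@dataclass
class REMLFit:
    """Variance components and derived quantities for one REML fit.

    ``h2`` is the realized proportion of phenotypic variance attributable to
    the additive term: sigma_a^2 kbar / (sigma_a^2 kbar + sigma_e^2) with
    kbar = tr(K)/n. For a kinship with unit mean diagonal (pedigree A, or a
    standardized G) this is the familiar sigma_a^2 / (sigma_a^2 + sigma_e^2);
    for a raw VanRaden G built from the sample allele frequencies of a
    family-structured population (mean diagonal below 1) the kbar factor
    keeps h2 on the phenotypic-variance scale.
    """

    sigma_a2: float
    sigma_e2: float
    h2: float
    h2_se: float
    logL_M: float
    logL_0: float
    blup_a: np.ndarray
    fixed_effects: np.ndarray
    n: int
    converged: bool = True
    boundary: bool = False  # delta pinned at a bound (h2 ~ 0 or ~ 1)
    identifiable: bool = True  # False for K = I, X = intercept only

    @property
    def r2_lr(self) -> float:
        return r2_lr(self.logL_M, self.logL_0, self.n)


def restricted_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> float:
    """Restricted log-likelihood of y ~ N(X beta, V) at fixed V (direct form)."""
    n, q = X.shape
    L = np.linalg.cholesky(V)
    ty = np.linalg.solve(L, y)
    tX = np.linalg.solve(L, X)
    XtViX = tX.T @ tX
    beta = np.linalg.solve(XtViX, tX.T @ ty)
    r = ty - tX @ beta
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    s, logdetXtViX = np.linalg.slogdet(XtViX)
    return -0.5 * (
        (n - q) * np.log(2 * np.pi) + logdetV + logdetXtViX + float(r @ r)
    )


def loglik_null(y: np.ndarray, X: np.ndarray | None = None) -> float:
    """Maximized restricted log-likelihood of the fixed-effects-only model.

    For the intercept-only model y = mu 1_n + e this is the closed form
    -1/2 [ (n-1)(log(2 pi s2) + 1) + log n ] with s2 = RSS / (n-1).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    q = X.shape[1]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    if rss <= 0:
        raise ValueError("degenerate (constant) phenotype")
    s2 = rss / (n - q)
    _, logdetXtX = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - q) * (np.log(2 * np.pi * s2) + 1.0) + logdetXtX)


def r2_lr(logL_M: float, logL_0: float, n: int) -> float:
    """Likelihood-ratio variance explained: 1 - exp(-2/n (logL_M - logL_0)).

    Equals the classical coefficient of determination when both likelihoods
    come from fixed-effects-only ML regressions. Clamped to 0 (with a warning)
    if logL_M < logL_0.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if logL_M < logL_0:
        warnings.warn("logL_M < logL_0; clamping R2_LR to 0", stacklevel=2)
        return 0.0
    return 1.0 - np.exp(-2.0 / n * (logL_M - logL_0))


def _profile_reml(lam, eta2, n, q, logdetXtX):
    """Profile restricted log-likelihood over delta given eigen summaries."""

    def negll(log_delta):
        delta = np.exp(log_delta)
        sa2 = np.sum(eta2 / (lam + delta)) / (n - q)
        ll = -0.5 * (
            (n - q) * (np.log(2 * np.pi) + np.log(sa2) + 1.0)
            + np.sum(np.log(lam + delta))
            + logdetXtX
        )
        return -ll

    grid = np.log(np.logspace(
        np.log10(_DELTA_BOUNDS[0]), np.log10(_DELTA_BOUNDS[1]), _GRID_POINTS
    ))
    vals = np.array([negll(g) for g in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        negll, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x)), -float(res.fun)


def _h2_se_expected_info(K, V, X, sa2, se2, kbar):
    """Delta-method SE of h2 from the expected (Fisher) information of REML."""
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    PK = P @ K
    I11 = 0.5 * np.sum(PK * PK.T)         # tr(PKPK)
    I12 = 0.5 * np.sum(PK * P.T)          # tr(PKP)
    I22 = 0.5 * np.sum(P * P.T)           # tr(PP)
    info = np.array([[I11, I12], [I12, I22]])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:  # pragma: no cover
        return float("nan")
    tot = sa2 * kbar + se2
    grad = np.array([kbar * se2, -kbar * sa2]) / tot**2
    var = float(grad @ cov @ grad)
    return float(np.sqrt(var)) if var > 0 else float("nan")


def reml_fit(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    X: np.ndarray | None = None,
    compute_se: bool = True,
) -> REMLFit:
    """REML fit of the single-random-effect mixed model via eigendecomposition.

    Individuals with missing phenotype are dropped, consistently from K's rows
    and columns. K must be positive semi-definite (blend a raw genomic G
    first). Returns variance components, h2 with approximate SE, BLUP breeding
    values for the retained individuals, and restricted log-likelihoods of the
    fitted and intercept-only models.
    """
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) != Kv.shape[0]:
        raise ValueError("phenotype length does not match kinship dimension")
    obs = ~np.isnan(y)
    if np.isinf(y[obs]).any():
        raise ValueError("non-finite phenotype values")
    y = y[obs]
    Kv = Kv[np.ix_(obs, obs)]
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    else:
        X = np.asarray(X, dtype=float)[obs] if X.shape[0] == len(obs) else X
        if X.shape[0] != n:
            raise ValueError("fixed-effect matrix rows do not match phenotypes")
    q = X.shape[1]
    if np.linalg.matrix_rank(X) < q:
        raise ValueError("fixed-covariate matrix is rank deficient")

    identifiable = not (q == 1 and np.ptp(X) == 0 and np.allclose(Kv, np.eye(n)))

    XtX = X.T @ X
    _, logdetXtX = np.linalg.slogdet(XtX)
    S = np.eye(n) - X @ np.linalg.solve(XtX, X.T)
    w, U = np.linalg.eigh(S @ Kv @ S)
    if w[0] < -1e-6 * max(1.0, w[-1]):
        raise ValueError("kinship matrix is not PSD; blend before fitting")
    lam = np.clip(w[q:], 0.0, None)
    eta = U[:, q:].T @ y
    eta2 = eta**2

    delta, logL_M = _profile_reml(lam, eta2, n, q, logdetXtX)
    boundary = (
        delta <= _DELTA_BOUNDS[0] * (1 + 1e-6) or delta >= _DELTA_BOUNDS[1] * (1 - 1e-6)
    )
    sa2 = float(np.sum(eta2 / (lam + delta)) / (n - q))
    se2 = float(delta * sa2)
    kbar = float(np.trace(Kv) / n)
    h2 = sa2 * kbar / (sa2 * kbar + se2)

    V = sa2 * Kv + se2 * np.eye(n)
    Vi_chol = np.linalg.cholesky(V)
    ty = np.linalg.solve(Vi_chol, y)
    tX = np.linalg.solve(Vi_chol, X)
    XtViX = tX.T @ tX
    beta = np.linalg.solve(XtViX, tX.T @ ty)
    resid = y - X @ beta
    Vinv_resid = np.linalg.solve(Vi_chol.T, np.linalg.solve(Vi_chol, resid))
    blup = sa2 * (Kv @ Vinv_resid)

    logL_0 = loglik_null(y)
    h2_se = (
        _h2_se_expected_info(Kv, V, X, sa2, se2, kbar)
        if compute_se
        else float("nan")
    )
    if not identifiable:
        warnings.warn(
            "K = I with intercept-only fixed effects: only sigma_a2 + sigma_e2 "
            "is identifiable; h2 is arbitrary",
            stacklevel=2,
        )
    return REMLFit(
        sigma_a2=sa2,
        sigma_e2=se2,
        h2=h2,
        h2_se=h2_se,
        logL_M=logL_M,
        logL_0=logL_0,
        blup_a=blup,
        fixed_effects=beta,
        n=n,
        boundary=boundary,
        identifiable=identifiable,
    )
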