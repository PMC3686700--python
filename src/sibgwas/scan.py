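"""EMMAX-style single-SNP association scan under the unified mixed model.

The null model y = X beta + a + e (X = intercept + selected genotype PCs,
a ~ N(0, K sigma_a^2)) is fitted once by REML; its variance components are
then held fixed across SNPs (the EMMAX approximation) and each SNP is tested
by generalized least squares: whiten with the Cholesky factor of
V = sigma_a^2 K + sigma_e^2 I, residualize against the base covariates, and
t-test the SNP coefficient with n - #fixed-parameters degrees of freedom.

Per-SNP and joint R2_LR contributions use the profile (GLS) likelihood at the
null variance components, so the likelihood-ratio variance-explained of a SNP
reduces to its partial R-squared in the whitened space, and a joint fit of
several SNPs is never below the best single SNP (nested-model monotonicity).
An exact mode re-estimates the variance components per SNP for oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix
from .mixedmodel import REMLFit, reml_fit
from .relatedness import KinshipMatrix, pca_genotypes

__all__ = [
    "ScanResult",
    "select_pcs_bic",
    "emmax_scan",
    "exact_scan",
    "genomewide_threshold",
    "per_test_alpha",
    "joint_r2",
    "qq_data",
]

DEFAULT_THRESHOLD = 5e-7  # per-test genome-wide significance (comparison-wise)


@dataclass
class ScanResult:
    """Per-SNP association statistics plus scan metadata."""

    table: pd.DataFrame  # snp_id, lg, bp, effect, se, t, p, neglog10p, r2lr, significant
    n: int
    n_pcs: int
    delta: float  # sigma_e2 / sigma_a2 from the null fit
    threshold: float
    null_fit: REMLFit | None = field(default=None, repr=False)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def genomewide_threshold(per_test: float, n_snps: int) -> float:
    """Implied genome-wide level of a per-test alpha (Bonferroni product)."""
    if not 0 < per_test < 1:
        raise ValueError("per-test alpha must lie in (0, 1)")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    gw = per_test * n_snps
    if gw > 1:
        raise ValueError(
            f"per-test alpha x n_snps = {gw:.3g} exceeds 1; not a valid level"
        )
    return gw


def per_test_alpha(genome_wide: float, n_snps: int) -> float:
    """Inverse of :func:`genomewide_threshold`."""
    if not 0 < genome_wide <= 1:
        raise ValueError("genome-wide alpha must lie in (0, 1]")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    return genome_wide / n_snps


def _whiten(y, X, K, fit):
    V = fit.sigma_a2 * K + fit.sigma_e2 * np.eye(len(y))
    L = np.linalg.cholesky(V)
    return np.linalg.solve(L, y), np.linalg.solve(L, X)


def _base_projection(tX):
    Q, _ = np.linalg.qr(tX)
    return Q


def select_pcs_bic(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    pcs: np.ndarray,
    max_pcs: int,
) -> int:
    """Forward BIC selection of the number of leading PC covariates.

    Fits the no-SNP mixed model with 0..max_pcs leading PCs; BIC =
    -2 logL + k log(n) with k the fixed-effect parameter count and logL the
    ML log-likelihood at the REML variance estimates (comparable across fixed
    parts). Ties break toward fewer PCs.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if max_pcs >= n:
        raise ValueError("max_pcs must be smaller than the sample size")
    if max_pcs == 0:
        return 0
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K)
    best_k, best_bic = 0, np.inf
    for k in range(max_pcs + 1):
        X = np.column_stack([np.ones(n)] + [pcs[:, j] for j in range(k)])
        fit = reml_fit(y, Kv, X, compute_se=False)
        V = fit.sigma_a2 * Kv + fit.sigma_e2 * np.eye(n)
        L = np.linalg.cholesky(V)
        ty = np.linalg.solve(L, y)
        tX = np.linalg.solve(L, X)
        beta = np.linalg.lstsq(tX, ty, rcond=None)[0]
        r = ty - tX @ beta
        logdetV = 2 * np.sum(np.log(np.diag(L)))
        ll_ml = -0.5 * (n * np.log(2 * np.pi) + logdetV + float(r @ r))
        bic = -2.0 * ll_ml + (k + 1) * np.log(n)
        if bic < best_bic - 1e-9:
            best_bic, best_k = bic, k
    return best_k


def emmax_scan(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    g: GenotypeMatrix,
    n_pcs: int = 0,
    pcs: np.ndarray | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    null_fit: REMLFit | None = None,
) -> ScanResult:
    """Single-SNP scan with null-model variance components held fixed.

    Monomorphic SNPs yield missing (NaN) rows rather than failures. The
    ``r2lr`` column is the SNP's likelihood-ratio variance-explained beyond
    the base (intercept + PCs + kinship) model.
    """
    y = np.asarray(y, dtype=float)
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K)
    n = len(y)
    if np.isnan(y).any():
        raise ValueError("drop or impute missing phenotypes before scanning")
    if n_pcs > 0 and pcs is None:
        pcs, _ = pca_genotypes(g, n_pcs)
    X = (
        np.column_stack([np.ones(n), pcs[:, :n_pcs]])
        if n_pcs > 0
        else np.ones((n, 1))
    )
    if null_fit is None:
        null_fit = reml_fit(y, Kv, X, compute_se=False)
    ty, tX = _whiten(y, X, Kv, null_fit)
    Q = _base_projection(tX)
    ry = ty - Q @ (Q.T @ ty)

    D = g.dosages
    if np.isnan(D).any():
        raise ValueError("impute missing dosages before scanning")
    V = null_fit.sigma_a2 * Kv + null_fit.sigma_e2 * np.eye(n)
    L = np.linalg.cholesky(V)
    tS = np.linalg.solve(L, D)
    rS = tS - Q @ (Q.T @ tS)

    q = X.shape[1]
    df = n - q - 1
    ss = np.einsum("ij,ij->j", rS, rS)
    sy = rS.T @ ry
    rss0 = float(ry @ ry)
    mono = D.std(axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sy / ss
        rss1 = rss0 - sy**2 / ss
        sigma2 = rss1 / df
        se = np.sqrt(sigma2 / ss)
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    r2lr = 1.0 - rss1 / rss0
    for arr in (beta, se, tstat, pvals, r2lr):
        arr[mono] = np.nan
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    with np.errstate(invalid="ignore"):
        neglog = -np.log10(pvals)
    sig = np.where(np.isnan(pvals), False, pvals < threshold)
    table = pd.DataFrame(
        {
            "snp_id": g.snp_ids,
            "lg": g.marker_map["lg"].to_numpy(),
            "bp": g.marker_map["bp"].to_numpy(),
            "effect": beta,
            "se": se,
            "t": tstat,
            "p": pvals,
            "neglog10p": neglog,
            "r2lr": r2lr,
            "significant": sig,
        }
    )
    table.loc[mono, "p"] = np.nan
    table.loc[mono, "neglog10p"] = np.nan
    return ScanResult(
        table=table,
        n=n,
        n_pcs=n_pcs,
        delta=null_fit.sigma_e2 / null_fit.sigma_a2,
        threshold=threshold,
        null_fit=null_fit,
    )


def exact_scan(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    g: GenotypeMatrix,
    n_pcs: int = 0,
    pcs: np.ndarray | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> ScanResult:
    """Exact per-SNP mixed-model scan: variance components re-estimated by
    REML for every SNP (oracle for the EMMAX approximation; O(m n^3))."""
    y = np.asarray(y, dtype=float)
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K)
    n = len(y)
    if n_pcs > 0 and pcs is None:
        pcs, _ = pca_genotypes(g, n_pcs)
    base = (
        np.column_stack([np.ones(n), pcs[:, :n_pcs]])
        if n_pcs > 0
        else np.ones((n, 1))
    )
    D = g.dosages
    rows = []
    for j in range(g.n_snps):
        snp = D[:, j]
        if snp.std() == 0:
            rows.append((np.nan,) * 4)
            continue
        X = np.column_stack([base, snp])
        fit = reml_fit(y, Kv, X, compute_se=False)
        V = fit.sigma_a2 * Kv + fit.sigma_e2 * np.eye(n)
        L = np.linalg.cholesky(V)
        ty, tX = np.linalg.solve(L, y), np.linalg.solve(L, X)
        XtX = tX.T @ tX
        beta = np.linalg.solve(XtX, tX.T @ ty)
        r = ty - tX @ beta
        dfree = n - X.shape[1]
        sigma2 = float(r @ r) / dfree
        cov = sigma2 * np.linalg.inv(XtX)
        se = np.sqrt(cov[-1, -1])
        tval = beta[-1] / se
        p = 2.0 * stats.t.sf(abs(tval), dfree)
        rows.append((beta[-1], se, tval, p))
    eff, se_, t_, p_ = map(np.array, zip(*rows))
    p_ = np.clip(p_, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "snp_id": g.snp_ids,
            "lg": g.marker_map["lg"].to_numpy(),
            "bp": g.marker_map["bp"].to_numpy(),
            "effect": eff,
            "se": se_,
            "t": t_,
            "p": p_,
            "neglog10p": -np.log10(p_),
            "r2lr": np.nan,
            "significant": p_ < threshold,
        }
    )
    return ScanResult(table, n, n_pcs, np.nan, threshold, None)


def _prune_significant(table: pd.DataFrame, window_bp: int) -> pd.DataFrame:
    """Greedy per-LG pruning: keep the largest-|t| SNP, drop neighbours within
    window_bp, repeat; ties break toward the smaller bp position."""
    sig = table[table["significant"]].copy()
    kept = []
    for lg, grp in sig.groupby("lg"):
        grp = grp.assign(abst=grp["t"].abs()).sort_values(
            ["abst", "bp"], ascending=[False, True]
        )
        taken: list[int] = []
        for row in grp.itertuples():
            if all(abs(row.bp - table.loc[i, "bp"]) > window_bp for i in taken):
                taken.append(row.Index)
        kept.extend(taken)
    return table.loc[sorted(kept)]


def joint_r2(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    g: GenotypeMatrix,
    scan: ScanResult,
    window_bp: int = 5_000_000,
    n_pcs: int | None = None,
    pcs: np.ndarray | None = None,
) -> dict:
    """Joint R2_LR of window-pruned genome-wide-significant SNPs.

    Among significant SNPs, the largest-|t| SNP per 5-Mb window per linkage
    group is kept; the kept SNPs are fitted together as fixed effects (at the
    null variance components) and the joint likelihood-ratio variance
    explained beyond the base model is returned. No significant SNPs -> 0.
    """
    y = np.asarray(y, dtype=float)
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K)
    n = len(y)
    if n_pcs is None:
        n_pcs = scan.n_pcs
    if n_pcs > 0 and pcs is None:
        pcs, _ = pca_genotypes(g, n_pcs)
    X = (
        np.column_stack([np.ones(n), pcs[:, :n_pcs]])
        if n_pcs > 0
        else np.ones((n, 1))
    )
    pruned = _prune_significant(scan.table, window_bp)
    if pruned.empty:
        return {"joint_r2lr": 0.0, "kept_snps": [], "note": "no significant SNPs"}
    fit = scan.null_fit or reml_fit(y, Kv, X, compute_se=False)
    ty, tX = _whiten(y, X, Kv, fit)
    Q = _base_projection(tX)
    ry = ty - Q @ (Q.T @ ty)
    idx = [g.marker_map.index[g.marker_map["snp_id"] == s][0] for s in pruned["snp_id"]]
    V = fit.sigma_a2 * Kv + fit.sigma_e2 * np.eye(n)
    L = np.linalg.cholesky(V)
    tS = np.linalg.solve(L, g.dosages[:, idx])
    rS = tS - Q @ (Q.T @ tS)
    coef, *_ = np.linalg.lstsq(rS, ry, rcond=None)
    rss1 = float(np.sum((ry - rS @ coef) ** 2))
    rss0 = float(ry @ ry)
    return {
        "joint_r2lr": 1.0 - rss1 / rss0,
        "kept_snps": list(pruned["snp_id"]),
    }


def qq_data(scan: ScanResult) -> dict:
    """Expected vs observed -log10 p under the null, plus genomic inflation.

    lambda_GC = median(chi2_1 quantiles of observed p) / median of chi2_1.
    """
    p = scan.table["p"].dropna().to_numpy()
    m = len(p)
    obs = np.sort(-np.log10(p))
    exp = -np.log10((np.arange(1, m + 1) - 0.5) / m)[::-1]
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
    return {"expected": exp, "observed": obs, "lambda_gc": lam}
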