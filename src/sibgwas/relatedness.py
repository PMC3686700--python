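"""Pedigree-expected (A) and marker-realized (G) relationship matrices.

A is the numerator relationship matrix from the tabular (recursive) method;
G follows VanRaden's method 1, G = M M' / (2 sum p_i q_i), with dosage columns
centered by twice the observed allele frequency. A genotype PCA for population
structure and an element-wise A-vs-G comparison round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import GenotypeMatrix, PedigreeTable, UNKNOWN_PARENT

__all__ = [
    "KinshipMatrix",
    "pedigree_A",
    "vanraden_G",
    "blend",
    "pca_genotypes",
    "compare_A_G",
]


@dataclass
class KinshipMatrix:
    """Symmetric n x n matrix of coefficients of relationship."""

    values: np.ndarray
    ids: np.ndarray
    kind: str  # pedigree_A | genomic_G | blended

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, keep_ids) -> "KinshipMatrix":
        pos = {v: i for i, v in enumerate(self.ids)}
        idx = np.array([pos[k] for k in keep_ids], dtype=int)
        return KinshipMatrix(self.values[np.ix_(idx, idx)], self.ids[idx], self.kind)

    def save(self, path) -> None:
        np.savez(path, values=self.values, ids=self.ids.astype(str), kind=self.kind)

    @classmethod
    def load(cls, path) -> "KinshipMatrix":
        with np.load(path, allow_pickle=False) as z:
            return cls(z["values"], z["ids"].astype(object), str(z["kind"]))


def pedigree_A(ped: PedigreeTable) -> KinshipMatrix:
    """Numerator relationship matrix by the tabular method.

    A_ii = 1 + F_i with inbreeding F_i = A_{sire,dam} / 2 (0 for unknown
    parents); A_ij = (A_{j,sire(i)} + A_{j,dam(i)}) / 2, processing
    individuals in an order where parents precede offspring.
    """
    order = ped.topological_order()
    idx = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    parents = {
        row.id: (row.sire, row.dam) for row in ped.records.itertuples()
    }
    for i, ind in enumerate(order):
        sire, dam = parents[ind]
        si = idx.get(sire) if sire != UNKNOWN_PARENT else None
        di = idx.get(dam) if dam != UNKNOWN_PARENT else None
        if sire != UNKNOWN_PARENT and si is None:
            raise ValueError(f"parent {sire!r} of {ind!r} not in pedigree")
        if dam != UNKNOWN_PARENT and di is None:
            raise ValueError(f"parent {dam!r} of {ind!r} not in pedigree")
        for j in range(i):
            a = 0.0
            if si is not None:
                a += A[j, si]
            if di is not None:
                a += A[j, di]
            A[i, j] = A[j, i] = a / 2.0
        f = A[si, di] / 2.0 if (si is not None and di is not None) else 0.0
        A[i, i] = 1.0 + f
    # return in the pedigree's original record order
    rec_ids = ped.ids
    perm = np.array([idx[i] for i in rec_ids], dtype=int)
    return KinshipMatrix(A[np.ix_(perm, perm)], rec_ids, "pedigree_A")


def centered_dosage_matrix(g: GenotypeMatrix) -> tuple[np.ndarray, float]:
    """VanRaden's M (dosages centered by 2 p_i) and the scaling 2 sum p_i q_i.

    Entries per column are 2q_i, q_i - p_i and -2p_i for the AA, AB and BB
    genotypes. Requires imputed (no missing) dosages and polymorphic SNPs.
    """
    d = g.dosages
    if np.isnan(d).any():
        raise ValueError("missing dosages present; impute before building G")
    p = d.mean(axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        bad = g.snp_ids[(p <= 0) | (p >= 1)]
        raise ValueError(f"monomorphic SNP(s) present: {list(bad[:5])}")
    M = d - 2.0 * p
    scale = 2.0 * np.sum(p * (1.0 - p))
    return M, scale


def vanraden_G(g: GenotypeMatrix) -> KinshipMatrix:
    """Realized relationship matrix G = M M' / (2 sum p_i q_i).

    Uses observed sample allele frequencies (VanRaden method 1). Because M's
    columns are centered with sample frequencies, the ones vector lies in G's
    null space: blend before inverting.
    """
    M, scale = centered_dosage_matrix(g)
    G = (M @ M.T) / scale
    return KinshipMatrix(G, g.ids, "genomic_G")


def blend(gmat: KinshipMatrix, epsilon: float = 0.01) -> KinshipMatrix:
    """(1 - epsilon) G + epsilon I; positive definite for epsilon > 0, G PSD."""
    if not (0 <= epsilon < 1):
        raise ValueError("epsilon must lie in [0, 1)")
    if epsilon == 0:
        return KinshipMatrix(gmat.values.copy(), gmat.ids, gmat.kind)
    v = (1 - epsilon) * gmat.values + epsilon * np.eye(gmat.n)
    return KinshipMatrix(v, gmat.ids, "blended")


def pca_genotypes(
    g: GenotypeMatrix, k: int, standardize: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal components of the column-centered dosage matrix.

    Returns (scores, explained_variance_fraction). SNP-variance
    standardization is off by default (PCA of the raw genotype data matrix);
    enable ``standardize`` to scale columns to unit variance first. Sign
    convention: the largest-magnitude loading of each component is positive.
    """
    d = g.dosages
    if np.isnan(d).any():
        raise ValueError("missing dosages present; impute before PCA")
    if k > min(d.shape):
        raise ValueError("k exceeds min(n_individuals, n_snps)")
    X = d - d.mean(axis=0)
    if standardize:
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("monomorphic SNP present; cannot standardize")
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| positive per component
    for j in range(len(s)):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U[:, :k] * s[:k]
    total_var = np.sum(s**2)
    explained = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return scores, explained


def compare_A_G(a: KinshipMatrix, g: KinshipMatrix) -> dict:
    """Product-moment correlation and means of off-diagonal relationships.

    Both matrices must carry the same individuals in the same order; only the
    upper-triangle off-diagonal elements (the pairwise coefficients of
    relationship) enter the comparison.
    """
    if a.n != g.n or not np.array_equal(a.ids, g.ids):
        raise ValueError("kinship matrices must share ids and order")
    iu = np.triu_indices(a.n, k=1)
    av, gv = a.values[iu], g.values[iu]
    return {
        "element_correlation": float(np.corrcoef(av, gv)[0, 1]),
        "mean_pairwise_A": float(av.mean()),
        "mean_pairwise_G": float(gv.mean()),
    }
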