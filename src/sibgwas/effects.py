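"""SNP allele substitution effects from GBLUP breeding values, and
linkage-group-level decomposition of breeding values and genetic correlations.

Back-solving uses alpha = (2 sum p_i q_i)^-1 M' G^- a_hat, with M the
frequency-centered dosage matrix and G the VanRaden matrix built from the
same M. With the unblended G (which is singular by construction: the ones
vector is in its null space), the Moore-Penrose pseudoinverse makes the
GBLUP <-> RR-BLUP equivalence exact: M alpha reproduces a_hat to numerical
precision, and alpha equals the ridge-regression SNP effects with matched
shrinkage. With a blended G the reconstruction error is reported explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix
from .relatedness import KinshipMatrix, centered_dosage_matrix

__all__ = [
    "ASEVector",
    "LGBreakdown",
    "backsolve_ase",
    "rrblup_effects",
    "lg_decompose",
    "lg_genetic_correlations",
    "compare_ase",
]


@dataclass
class ASEVector:
    """Per-SNP allele substitution effects (trait units per counted allele)."""

    effects: np.ndarray
    snp_ids: np.ndarray
    counted_allele: str = "A"
    aggregation_error: float = 0.0  # max |M alpha - a_hat| (relative)

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if len(self.effects) != len(self.snp_ids):
            raise ValueError("one effect per SNP required")
        if not np.isfinite(self.effects).all():
            raise ValueError("non-finite allele substitution effects")

    def to_frame(self, marker_map: pd.DataFrame) -> pd.DataFrame:
        out = marker_map.copy()
        out["effect"] = self.effects
        return out


@dataclass
class LGBreakdown:
    """Per-individual, per-linkage-group partial breeding values."""

    partial_bv: pd.DataFrame  # index: individual ids; columns: lg labels
    total_bv: np.ndarray  # marker-based total BV (= M alpha)

    def __post_init__(self) -> None:
        s = self.partial_bv.sum(axis=1).to_numpy()
        if not np.allclose(s, self.total_bv, rtol=1e-8, atol=1e-10):
            raise ValueError("LG partial BVs do not sum to the total BV")


def backsolve_ase(
    blup_a: np.ndarray,
    g: GenotypeMatrix,
    G: KinshipMatrix | np.ndarray | None = None,
) -> ASEVector:
    """Back-solve SNP effects from GBLUP breeding values.

    ``G`` must be built from the same genotypes/frequencies as ``g`` (it is
    rebuilt internally when omitted). A singular (unblended) G is inverted
    with the pseudoinverse; a blended G with its regular inverse, in which
    case the aggregation error ``max |M alpha - a_hat| / max|a_hat|`` is
    reported on the result.
    """
    blup_a = np.asarray(blup_a, dtype=float)
    if len(blup_a) != g.n_individuals:
        raise ValueError("breeding-value vector does not match genotypes")
    M, scale = centered_dosage_matrix(g)
    if G is None:
        Gv = (M @ M.T) / scale
        blended = False
    else:
        Gv = G.values if isinstance(G, KinshipMatrix) else np.asarray(G)
        blended = isinstance(G, KinshipMatrix) and G.kind == "blended"
        if Gv.shape[0] != g.n_individuals:
            raise ValueError("kinship dimension does not match genotypes")
    if blended:
        Ginv_a = np.linalg.solve(Gv, blup_a)
    else:
        Ginv_a = np.linalg.pinv(Gv, hermitian=True) @ blup_a
    alpha = (M.T @ Ginv_a) / scale
    recon = M @ alpha
    denom = np.max(np.abs(blup_a)) or 1.0
    err = float(np.max(np.abs(recon - blup_a)) / denom)
    return ASEVector(alpha, g.snp_ids, aggregation_error=err)


def rrblup_effects(
    y_resid: np.ndarray,
    g: GenotypeMatrix,
    sigma_a2: float,
    sigma_e2: float,
) -> np.ndarray:
    """Direct ridge-regression (RR-BLUP) SNP effects with matched shrinkage.

    Solves alpha = (M'M + (sigma_e2 / sigma_alpha2) I)^-1 M' r with
    sigma_alpha2 = sigma_a2 / (2 sum p_i q_i) and r the fixed-effect-adjusted
    phenotype. Independent m x m route used as the oracle for
    :func:`backsolve_ase`.
    """
    M, scale = centered_dosage_matrix(g)
    lam = sigma_e2 / (sigma_a2 / scale)
    A = M.T @ M + lam * np.eye(M.shape[1])
    return np.linalg.solve(A, M.T @ np.asarray(y_resid, dtype=float))


def lg_decompose(ase: ASEVector, g: GenotypeMatrix) -> LGBreakdown:
    """Split each individual's marker-based BV into per-LG contributions.

    Uses centered dosages so partial BVs are mean-zero per linkage group;
    their sum across LGs equals the total M alpha exactly.
    """
    if len(ase.effects) != g.n_snps:
        raise ValueError("effect vector length does not match SNP count")
    if not np.array_equal(ase.snp_ids, g.snp_ids):
        raise ValueError("effect vector SNP ids do not match genotypes")
    M, _ = centered_dosage_matrix(g)
    lgs = g.marker_map["lg"].to_numpy()
    cols = {}
    for lg in np.unique(lgs):
        sel = lgs == lg
        cols[int(lg)] = M[:, sel] @ ase.effects[sel]
    partial = pd.DataFrame(cols, index=g.ids)
    total = M @ ase.effects
    return LGBreakdown(partial, total)


def lg_genetic_correlations(bkA: LGBreakdown, bkB: LGBreakdown) -> pd.DataFrame:
    """Per-LG and genome-level genetic correlations between two traits.

    Per LG: product-moment correlation across individuals of the LG partial
    breeding values; genome level: correlation of the total BVs. Zero-variance
    partial BVs yield NaN for that linkage group.
    """
    if not bkA.partial_bv.index.equals(bkB.partial_bv.index):
        raise ValueError("breakdowns must cover the same individuals")
    if list(bkA.partial_bv.columns) != list(bkB.partial_bv.columns):
        raise ValueError("breakdowns must cover the same linkage groups")
    rows = []
    for lg in bkA.partial_bv.columns:
        a = bkA.partial_bv[lg].to_numpy()
        b = bkB.partial_bv[lg].to_numpy()
        if a.std() == 0 or b.std() == 0:
            rows.append((lg, np.nan))
        else:
            rows.append((lg, float(np.corrcoef(a, b)[0, 1])))
    genome = float(np.corrcoef(bkA.total_bv, bkB.total_bv)[0, 1])
    rows.append(("genome", genome))
    return pd.DataFrame(rows, columns=["lg", "r_g"])


def compare_ase(single_snp: np.ndarray, all_snp: ASEVector | np.ndarray) -> dict:
    """Product-moment correlation between single-SNP-scan effects and
    all-SNP (back-solved) effects over the same SNP set and coding."""
    a = np.asarray(single_snp, dtype=float)
    b = all_snp.effects if isinstance(all_snp, ASEVector) else np.asarray(all_snp)
    if len(a) != len(b):
        raise ValueError("effect vectors must cover the same SNPs")
    ok = np.isfinite(a) & np.isfinite(b)
    r = float(np.corrcoef(a[ok], b[ok])[0, 1])
    return {"correlation": r, "n_snps": int(ok.sum()), "single": a, "all": b}
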