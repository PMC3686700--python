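"""Pairwise linkage disequilibrium (r^2) and distance-binned decay profiles.

The default estimator is the composite (dosage-correlation-squared) r^2,
appropriate for unphased genotypes; a haplotype-frequency estimator
D^2 / (pA pa pB pb) is available for phased input. Decay profiles bin all
within-linkage-group SNP pairs by physical distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix

__all__ = [
    "LDDecayProfile",
    "pairwise_r2",
    "haplotype_r2",
    "decay_profile",
    "compare_profiles",
]


@dataclass
class LDDecayProfile:
    """Mean r^2 and pair counts per half-open distance bin [lo, hi)."""

    bin_lo: np.ndarray  # bp
    bin_hi: np.ndarray
    mean_r2: np.ndarray  # NaN for empty bins
    n_pairs: np.ndarray
    population: str = ""

    def __post_init__(self) -> None:
        if np.any(self.bin_lo[1:] < self.bin_hi[:-1] - 1e-9):
            raise ValueError("bins must be sorted and non-overlapping")
        if np.any(self.n_pairs < 0):
            raise ValueError("pair counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_lo,
                "bin_hi": self.bin_hi,
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs,
            }
        )


def pairwise_r2(
    g: GenotypeMatrix, snp_i: str, snp_j: str, method: str = "composite"
) -> float:
    """r^2 between two SNPs: squared dosage correlation (composite method)."""
    if method == "haplotype":
        raise ValueError(
            "haplotype method needs phased input; use haplotype_r2(haps, i, j)"
        )
    if method != "composite":
        raise ValueError(f"unknown LD method {method!r}")
    ids = list(g.snp_ids)
    a = g.dosages[:, ids.index(snp_i)]
    b = g.dosages[:, ids.index(snp_j)]
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic SNP in r2 computation")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def haplotype_r2(haplotypes: np.ndarray, i: int, j: int) -> float:
    """Haplotype-frequency r^2 = D^2 / (pA pa pB pb) from phased 0/1 alleles.

    ``haplotypes`` is a (n_haplotypes, m) array; columns i, j are the two loci.
    """
    a = haplotypes[:, i].astype(float)
    b = haplotypes[:, j].astype(float)
    pA, pB = a.mean(), b.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic locus in haplotype r2")
    pAB = np.mean(a * b)
    D = pAB - pA * pB
    return float(D**2 / (pA * (1 - pA) * pB * (1 - pB)))


def decay_profile(
    g: GenotypeMatrix,
    bins: int | np.ndarray = 20,
    max_dist_bp: int = 5_000_000,
    within_lg_only: bool = True,
    population: str = "",
) -> LDDecayProfile:
    """Genome-wide LD decay: mean composite r^2 per distance bin.

    All within-linkage-group SNP pairs closer than ``max_dist_bp`` are
    assigned to half-open bins; empty bins are reported with NaN means, never
    dropped. ``bins`` is either an edge array or a count of equal-width bins
    over [0, max_dist_bp).
    """
    if not within_lg_only:
        raise ValueError("between-LG pairs have no physical distance")
    edges = (
        np.asarray(bins, dtype=float)
        if not np.isscalar(bins)
        else np.linspace(0, max_dist_bp, int(bins) + 1)
    )
    nbins = len(edges) - 1
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=int)
    lgs = g.marker_map["lg"].to_numpy()
    bps = g.marker_map["bp"].to_numpy()
    d = g.dosages
    for lg in np.unique(lgs):
        sel = np.flatnonzero(lgs == lg)
        if sel.size < 2:
            continue
        sub = d[:, sel]
        ok = ~np.isnan(sub)
        # pairwise complete-case correlation via masked arrays
        sub_m = np.ma.masked_invalid(sub)
        corr = np.ma.corrcoef(sub_m, rowvar=False)
        r2 = np.asarray(corr.filled(np.nan)) ** 2
        pos = bps[sel]
        dist = np.abs(pos[:, None] - pos[None, :])
        iu = np.triu_indices(sel.size, k=1)
        dd, rr = dist[iu], r2[iu]
        keep = (dd < max_dist_bp) & ~np.isnan(rr)
        dd, rr = dd[keep], rr[keep]
        which = np.searchsorted(edges, dd, side="right") - 1
        inside = (which >= 0) & (which < nbins)
        np.add.at(sums, which[inside], rr[inside])
        np.add.at(counts, which[inside], 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayProfile(edges[:-1], edges[1:], means, counts, population)


def compare_profiles(p1: LDDecayProfile, p2: LDDecayProfile) -> dict:
    """Per-bin mean-r^2 differences and Spearman correlation of decay shapes.

    Bins must match exactly; bins empty in either profile propagate NaN
    differences and are excluded from the rank correlation.
    """
    if not (
        np.array_equal(p1.bin_lo, p2.bin_lo) and np.array_equal(p1.bin_hi, p2.bin_hi)
    ):
        raise ValueError("profiles must share bin definitions")
    delta = p1.mean_r2 - p2.mean_r2
    ok = np.isfinite(p1.mean_r2) & np.isfinite(p2.mean_r2)
    rho = (
        float(stats.spearmanr(p1.mean_r2[ok], p2.mean_r2[ok]).statistic)
        if ok.sum() >= 2
        else float("nan")
    )
    return {"delta_mean_r2": delta, "spearman": rho}
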