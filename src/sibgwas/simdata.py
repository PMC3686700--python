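"""Synthetic factorial-mating populations with realistic LD and pedigrees.

Emulates the structure of a seedling trial from a 4 x 2 factorial cross (one
cross failed, leaving seven full-sib families of 40-350 seedlings, ~1,200 in
total) genotyped at 2,500 SNPs spread over 17 linkage groups. Founder
haplotypes carry distance-decaying LD from a first-order copying process;
offspring are produced by meiosis with Poisson (Haldane, no-interference)
crossovers using a fixed bp-per-cM map scaling; a configurable fraction of
offspring receive their paternal gamete from an out-of-design pollen donor
while the recorded pedigree still lists the design father (pollen
contamination). Quantitative traits combine major-gene QTL, per-linkage-group
polygenic backgrounds and Gaussian noise, calibrated to a target narrow-sense
heritability; binary disorder traits are thresholded liabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, PedigreeTable, UNKNOWN_PARENT

__all__ = [
    "SimDesign",
    "TraitArchitecture",
    "FounderSet",
    "simulate_founder_haplotypes",
    "mate_factorial",
    "simulate_phenotypes",
    "derive_wci",
    "simulate_population",
]

# Default family sizes: seven realized crosses of a 4x2 factorial (one failed),
# sizes in the study's stated 40-350 range summing to 1,200 seedlings.
DEFAULT_FAMILY_SIZES = (350, 260, 200, 150, 110, 90, 40)


@dataclass
class SimDesign:
    """Design parameters of the simulated mating experiment.

    ``bp_per_cm`` converts physical to map distance (default 500,000 bp/cM,
    i.e. ~1 cM per 0.5 Mbp); ``ld_decay_bp`` is the correlation length of the
    founder copying process (copy probability exp(-d / ld_decay_bp); 0 means
    independent sites). ``contamination_rate`` is the fraction of offspring
    whose paternal gamete comes from an out-of-design pollen donor.
    """

    n_founders_female: int = 4
    n_founders_male: int = 2
    family_sizes: tuple = DEFAULT_FAMILY_SIZES
    n_lg: int = 17
    snps_per_lg: int = 147  # ~2,500 genome-wide
    lg_length_bp: int = 30_000_000
    bp_per_cm: float = 500_000.0
    ld_decay_bp: float = 500_000.0  # calibrated: offspring mean r2 at 500 kb ~ 0.25
    contamination_rate: float = 0.0
    n_contaminant_males: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_founders_female,
            self.n_founders_male,
            self.n_lg,
            self.snps_per_lg,
            self.lg_length_bp,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all design counts/lengths must be positive")
        if not self.family_sizes or any(s <= 0 for s in self.family_sizes):
            raise ValueError("family sizes must be positive")
        n_crosses = self.n_founders_female * self.n_founders_male
        if len(self.family_sizes) > n_crosses:
            raise ValueError("more families than possible crosses")
        if not 0 <= self.contamination_rate <= 1:
            raise ValueError("contamination_rate must lie in [0, 1]")
        if self.bp_per_cm <= 0 or self.ld_decay_bp < 0:
            raise ValueError("map scaling must be positive, LD decay >= 0")

    @property
    def n_offspring(self) -> int:
        return int(sum(self.family_sizes))

    @property
    def n_snps(self) -> int:
        return self.n_lg * self.snps_per_lg


@dataclass
class TraitArchitecture:
    """Multi-trait QTL architecture with optional pleiotropy.

    ``qtl_positions[t]`` lists (lg, bp) per trait; a QTL is tied to the
    nearest simulated SNP unless ``hidden_causal`` is set, in which case the
    causal locus sits between markers (its genotype is simulated but not
    reported), so marker-QTL LD is < 1. ``polygenic_share`` is the fraction of
    genetic variance spread over small-effect SNPs on every linkage group.
    """

    n_traits: int
    qtl_positions: list  # per trait: list of (lg, bp)
    qtl_effects: list  # per trait: list of additive effects (trait units/allele)
    h2: list  # per-trait narrow-sense heritability in (0,1)
    polygenic_share: list | None = None  # per-trait fraction of genetic var
    polygenic_spacing: int = 5  # small effects at every k-th SNP
    trait_names: list | None = None
    binary_threshold: dict = field(default_factory=dict)  # trait index -> liability quantile

    def __post_init__(self) -> None:
        if self.polygenic_share is None:
            self.polygenic_share = [0.5] * self.n_traits
        if self.trait_names is None:
            self.trait_names = [f"trait{t+1}" for t in range(self.n_traits)]
        for h in self.h2:
            if not 0 < h < 1:
                raise ValueError("h2 must lie in (0, 1)")
        for s in self.polygenic_share:
            if not 0 <= s <= 1:
                raise ValueError("polygenic share must lie in [0, 1]")
        lens = {len(self.qtl_positions), len(self.qtl_effects), len(self.h2)}
        if lens != {self.n_traits}:
            raise ValueError("per-trait lists must all have n_traits entries")


@dataclass
class FounderSet:
    """Phased founder haplotypes: (2 * n_founders, m) arrays of 0/1 alleles."""

    females: np.ndarray
    males: np.ndarray
    contaminants: np.ndarray
    marker_map: pd.DataFrame

    @property
    def all_design(self) -> np.ndarray:
        return np.vstack([self.females, self.males])


def _marker_map(design: SimDesign) -> pd.DataFrame:
    rows = []
    for lg in range(1, design.n_lg + 1):
        bp = np.sort(
            np.linspace(1, design.lg_length_bp, design.snps_per_lg, dtype=int)
        )
        for j, b in enumerate(bp):
            rows.append((f"LG{lg:02d}_S{j+1:04d}", lg, int(b)))
    return pd.DataFrame(rows, columns=["snp_id", "lg", "bp"])


def _copying_haplotypes(rng, n_hap, mm, base_freq, ld_decay_bp):
    """First-order copying process: allele j+1 copies allele j with
    probability exp(-d/L), else is a fresh Bernoulli draw."""
    m = len(mm)
    hap = np.empty((n_hap, m), dtype=np.int8)
    lgs = mm["lg"].to_numpy()
    bps = mm["bp"].to_numpy()
    u = rng.random((n_hap, m))
    copy_u = rng.random((n_hap, m))
    for j in range(m):
        fresh = (u[:, j] < base_freq[j]).astype(np.int8)
        if j == 0 or lgs[j] != lgs[j - 1]:
            hap[:, j] = fresh
            continue
        d = bps[j] - bps[j - 1]
        c = np.exp(-d / ld_decay_bp) if ld_decay_bp > 0 else 0.0
        take_prev = copy_u[:, j] < c
        hap[:, j] = np.where(take_prev, hap[:, j - 1], fresh)
    return hap


def simulate_founder_haplotypes(design: SimDesign) -> FounderSet:
    """Phased founder haplotypes with distance-decaying LD.

    Base allele frequencies are drawn uniformly in [0.1, 0.9] (realized
    frequencies stay bounded away from 0 and 1); contaminant pollen donors are
    drawn from a frequency-shifted pool so genotype PCA can separate their
    offspring from the design families.
    """
    rng = np.random.default_rng(design.seed)
    mm = _marker_map(design)
    m = len(mm)
    base = rng.uniform(0.1, 0.9, size=m)
    females = _copying_haplotypes(
        rng, 2 * design.n_founders_female, mm, base, design.ld_decay_bp
    )
    males = _copying_haplotypes(
        rng, 2 * design.n_founders_male, mm, base, design.ld_decay_bp
    )
    # contaminants: same LD machinery, shifted frequency spectrum
    shift = rng.uniform(-0.35, 0.35, size=m)
    base_c = np.clip(base + shift, 0.05, 0.95)
    contaminants = _copying_haplotypes(
        rng, 2 * design.n_contaminant_males, mm, base_c, design.ld_decay_bp
    )
    return FounderSet(females, males, contaminants, mm)


def _meiosis(rng, hap_pair, mm, bp_per_cm):
    """One gamete from a phased diploid parent; Poisson crossovers per LG
    (Haldane: map length in Morgan = LG bp span / bp_per_cm / 100), uniform
    crossover placement, no interference."""
    m = hap_pair.shape[1]
    gamete = np.empty(m, dtype=np.int8)
    lgs = mm["lg"].to_numpy()
    bps = mm["bp"].to_numpy()
    for lg in np.unique(lgs):
        sel = lgs == lg
        pos = bps[sel]
        span = pos[-1] - pos[0]
        morgans = span / bp_per_cm / 100.0
        n_cross = rng.poisson(morgans)
        current = rng.integers(2)
        if n_cross == 0:
            phase = np.full(sel.sum(), current)
        else:
            xs = np.sort(rng.uniform(pos[0], pos[-1], size=n_cross))
            phase = (current + np.searchsorted(xs, pos)) % 2
        src = hap_pair[:, sel]
        gamete[sel] = src[phase, np.arange(sel.sum())]
    return gamete


def mate_factorial(
    founders: FounderSet, design: SimDesign, return_haplotypes: bool = False
):
    """Offspring genotypes + pedigree from the factorial mating design.

    Families are assigned to (female, male) cross combinations in order,
    skipping the last cross when fewer families than crosses are requested
    (the failed cross). A ``contamination_rate`` fraction of offspring receive
    their paternal gamete from a random contaminant donor; the recorded
    pedigree still lists the design father. Returns the genotype matrix
    (founders included, parents first), the recorded pedigree, and a boolean
    contamination flag per offspring (truth, not part of the pedigree).
    """
    rng = np.random.default_rng(design.seed + 1)
    mm = founders.marker_map
    crosses = [
        (f, m)
        for f in range(design.n_founders_female)
        for m in range(design.n_founders_male)
    ]
    if len(design.family_sizes) > len(crosses):
        raise ValueError("family count inconsistent with design")
    crosses = crosses[: len(design.family_sizes)]

    female_ids = [f"F{i+1}" for i in range(design.n_founders_female)]
    male_ids = [f"M{i+1}" for i in range(design.n_founders_male)]
    ped_rows = [(i, UNKNOWN_PARENT, UNKNOWN_PARENT) for i in female_ids + male_ids]

    n_off = design.n_offspring
    m = len(mm)
    dosages = []
    # founder genotypes first
    for i in range(design.n_founders_female):
        dosages.append(founders.females[2 * i] + founders.females[2 * i + 1])
    for i in range(design.n_founders_male):
        dosages.append(founders.males[2 * i] + founders.males[2 * i + 1])

    contaminated = np.zeros(n_off, dtype=bool)
    contam_draw = rng.random(n_off) < design.contamination_rate
    ids = list(female_ids + male_ids)
    gametes = []  # offspring phased haplotypes (maternal, paternal)
    k = 0
    for fam, ((fi, mi), size) in enumerate(zip(crosses, design.family_sizes)):
        dam_pair = founders.females[2 * fi : 2 * fi + 2]
        sire_pair = founders.males[2 * mi : 2 * mi + 2]
        for _ in range(size):
            child = f"A{fam+1:02d}_{k+1:04d}"
            maternal = _meiosis(rng, dam_pair, mm, design.bp_per_cm)
            if contam_draw[k] and design.n_contaminant_males > 0:
                donor = rng.integers(design.n_contaminant_males)
                donor_pair = founders.contaminants[2 * donor : 2 * donor + 2]
                paternal = _meiosis(rng, donor_pair, mm, design.bp_per_cm)
                contaminated[k] = True
            else:
                paternal = _meiosis(rng, sire_pair, mm, design.bp_per_cm)
            dosages.append(maternal + paternal)
            gametes.append((maternal, paternal))
            ped_rows.append((child, male_ids[mi], female_ids[fi]))
            ids.append(child)
            k += 1

    g = GenotypeMatrix(np.array(dosages, dtype=float), np.array(ids, dtype=object), mm)
    ped = PedigreeTable(pd.DataFrame(ped_rows, columns=["id", "sire", "dam"]))
    if return_haplotypes:
        haps = np.array([h for pair in gametes for h in pair], dtype=np.int8)
        return g, ped, contaminated, haps
    return g, ped, contaminated


def _nearest_snp(mm: pd.DataFrame, lg: int, bp: int) -> int:
    sel = np.flatnonzero(mm["lg"].to_numpy() == lg)
    if sel.size == 0:
        raise ValueError(f"QTL position on unknown linkage group {lg}")
    j = sel[np.argmin(np.abs(mm["bp"].to_numpy()[sel] - bp))]
    return int(j)


def simulate_phenotypes(
    g: GenotypeMatrix,
    arch: TraitArchitecture,
    seed: int,
    offspring_only_ids: np.ndarray | None = None,
    with_genetic_values: bool = False,
):
    """Trait values = QTL effects + per-LG polygenic term + Gaussian noise.

    The residual is scaled against the realized genetic variance so the
    realized h2 matches ``arch.h2`` up to sampling error. Returns a tidy table
    (id + one column per trait); binary traits are thresholded liabilities.
    With ``with_genetic_values`` a second table holding the latent genetic
    values (before noise and thresholding) is returned as well.
    """
    rng = np.random.default_rng(seed)
    mm = g.marker_map
    d = g.dosages
    if np.isnan(d).any():
        raise ValueError("impute missing dosages before simulating phenotypes")
    n = g.n_individuals
    centered = d - d.mean(axis=0)
    out = {"id": g.ids}
    gvals = {"id": g.ids}
    for t in range(arch.n_traits):
        gval = np.zeros(n)
        for (lg, bp), eff in zip(arch.qtl_positions[t], arch.qtl_effects[t]):
            j = _nearest_snp(mm, lg, bp)
            gval += centered[:, j] * eff
        share = arch.polygenic_share[t]
        if share > 0:
            # small effects at every k-th SNP on every LG, scaled to the share
            poly_idx = np.arange(0, g.n_snps, arch.polygenic_spacing)
            eff = rng.normal(size=poly_idx.size)
            poly = centered[:, poly_idx] @ eff
            v_q = np.var(gval)
            v_p = np.var(poly)
            if v_p > 0:
                if v_q > 0:
                    poly *= np.sqrt(share / (1 - share) * v_q / v_p)
                gval = gval + poly
        v_g = np.var(gval)
        h2 = arch.h2[t]
        if v_g == 0:
            y = rng.normal(size=n)  # pure-noise trait
        else:
            v_e = v_g * (1 - h2) / h2
            y = gval + rng.normal(scale=np.sqrt(v_e), size=n)
        tname = arch.trait_names[t]
        gvals[tname] = gval
        if t in arch.binary_threshold:
            thr = np.quantile(y, arch.binary_threshold[t])
            y = (y > thr).astype(float)
        out[tname] = y
    df = pd.DataFrame(out)
    gdf = pd.DataFrame(gvals)
    if offspring_only_ids is not None:
        keep = df["id"].isin(set(offspring_only_ids))
        df = df[keep].reset_index(drop=True)
        gdf = gdf[keep].reset_index(drop=True)
    return (df, gdf) if with_genetic_values else df


def derive_wci(pra: float | np.ndarray, ri: float | np.ndarray):
    """Weighted cortical intensity: proportion of red cortex area x red
    intensity score (0-9)."""
    pra = np.asarray(pra, dtype=float)
    ri = np.asarray(ri, dtype=float)
    if np.any(pra < 0) or np.any(ri < 0):
        raise ValueError("PRA and RI must be non-negative")
    if np.any(ri > 9):
        raise ValueError("RI score is bounded by 9")
    out = pra * ri
    return float(out) if out.ndim == 0 else out


def simulate_population(
    design: SimDesign, arch: TraitArchitecture | None = None
):
    """Convenience wrapper: founders -> factorial mating -> phenotypes.

    Returns (genotypes, pedigree, phenotypes or None, contaminated flags).
    Phenotypes are simulated on the full genotyped set (founders included).
    """
    founders = simulate_founder_haplotypes(design)
    g, ped, contaminated = mate_factorial(founders, design)
    phen = None
    if arch is not None:
        phen = simulate_phenotypes(g, arch, seed=design.seed + 2)
    return g, ped, phen, contaminated
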