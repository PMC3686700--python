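"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pytest

from sibgwas import (
    blend,
    drop_monomorphic,
    impute_missing,
    pedigree_A,
    vanraden_G,
)
from sibgwas.simdata import SimDesign, TraitArchitecture, simulate_population


@pytest.fixture(scope="session")
def small_pop():
    """Four full-sib families (~190 seedlings), 5 LGs x 60 SNPs, two traits
    sharing one opposite-sign QTL on LG2 plus independent polygenes."""
    design = SimDesign(
        family_sizes=(60, 50, 40, 30),
        n_lg=5,
        snps_per_lg=60,
        seed=11,
        contamination_rate=0.0,
    )
    arch = TraitArchitecture(
        n_traits=2,
        qtl_positions=[[(2, 15_000_000)], [(2, 15_000_000)]],
        qtl_effects=[[0.8], [-0.8]],
        h2=[0.4, 0.4],
        polygenic_share=[0.5, 0.5],
    )
    g, ped, phen, contaminated = simulate_population(design, arch)
    gi = impute_missing(drop_monomorphic(g))
    return {
        "design": design,
        "arch": arch,
        "genotypes_raw": g,
        "genotypes": gi,
        "pedigree": ped,
        "phenotypes": phen,
        "contaminated": contaminated,
    }


@pytest.fixture(scope="session")
def small_kinships(small_pop):
    gi = small_pop["genotypes"]
    G = vanraden_G(gi)
    Gb = blend(G, 0.01)
    A = pedigree_A(small_pop["pedigree"]).subset(gi.ids)
    return {"G": G, "G_blend": Gb, "A": A}


@pytest.fixture(scope="session")
def trait_vectors(small_pop):
    phen = small_pop["phenotypes"].set_index("id")
    ids = small_pop["genotypes"].ids
    y1 = phen["trait1"].reindex(ids).to_numpy(dtype=float)
    y2 = phen["trait2"].reindex(ids).to_numpy(dtype=float)
    return y1, y2


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
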