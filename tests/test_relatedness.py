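"""A-matrix recursion against textbook values and gene-dropping; VanRaden G
hand algebra and invariances; PCA structure; A-vs-G comparison."""

import numpy as np
import pandas as pd
import pytest

from sibgwas import (
    GenotypeMatrix,
    KinshipMatrix,
    PedigreeTable,
    blend,
    compare_A_G,
    pca_genotypes,
    pedigree_A,
    vanraden_G,
)
from sibgwas.simdata import SimDesign, simulate_founder_haplotypes, simulate_population
from sibgwas.genio import drop_monomorphic, impute_missing


def _ped(rows):
    return PedigreeTable(pd.DataFrame(rows, columns=["id", "sire", "dam"]))


class TestPedigreeA:
    def test_unrelated_founders_identity(self):
        A = pedigree_A(_ped([("a", "0", "0"), ("b", "0", "0")]))
        np.testing.assert_allclose(A.values, np.eye(2))

    def test_full_sib_and_parent_offspring_half(self):
        ped = _ped(
            [
                ("s", "0", "0"),
                ("d", "0", "0"),
                ("c1", "s", "d"),
                ("c2", "s", "d"),
            ]
        )
        A = pedigree_A(ped)
        ids = list(A.ids)
        i = {v: k for k, v in enumerate(ids)}
        assert A.values[i["c1"], i["c2"]] == pytest.approx(0.5)
        assert A.values[i["s"], i["c1"]] == pytest.approx(0.5)
        assert A.values[i["c1"], i["c1"]] == pytest.approx(1.0)

    def test_selfed_offspring_inbreeding(self):
        ped = _ped([("p", "0", "0"), ("x", "p", "p")])
        A = pedigree_A(ped)
        i = {v: k for k, v in enumerate(A.ids)}
        assert A.values[i["x"], i["x"]] == pytest.approx(1.5)

    def test_unknown_parent_id_rejected(self):
        with pytest.raises(ValueError, match="not in pedigree"):
            pedigree_A(_ped([("a", "ghost", "0")]))

    def test_matches_gene_dropping(self, rng):
        """The tabular A equals average realized IBD relationship over many
        gene-dropping replicates on a three-generation pedigree."""
        ped = _ped(
            [
                ("f1", "0", "0"),
                ("f2", "0", "0"),
                ("f3", "0", "0"),
                ("c1", "f1", "f2"),
                ("c2", "f1", "f2"),
                ("g1", "c1", "f3"),
                ("g2", "c1", "c2"),
            ]
        )
        A = pedigree_A(ped)
        order = ped.topological_order()
        reps = 20000
        alleles = {}
        counter = 0
        sums = np.zeros((len(order), len(order)))
        idx = {v: k for k, v in enumerate(A.ids)}
        parents = {
            r.id: (r.sire, r.dam) for r in ped.records.itertuples()
        }
        for _ in range(reps):
            alleles = {}
            for ind in order:
                s, d = parents[ind]
                a1 = (
                    alleles[s][rng.integers(2)]
                    if s != "0"
                    else (counter := counter + 1)
                )
                a2 = (
                    alleles[d][rng.integers(2)]
                    if d != "0"
                    else (counter := counter + 1)
                )
                alleles[ind] = (a1, a2)
            for i_name in order:
                for j_name in order:
                    ai, aj = alleles[i_name], alleles[j_name]
                    share = sum(x == y for x in ai for y in aj) / 4.0
                    sums[idx[i_name], idx[j_name]] += 2 * share  # relationship
        realized = sums / reps
        np.testing.assert_allclose(realized, A.values, atol=0.02)


class TestVanRadenG:
    def test_hand_worked_two_by_two(self):
        dos = np.array([[2.0, 0.0], [0.0, 2.0]])
        mm = pd.DataFrame({"snp_id": ["a", "b"], "lg": [1, 1], "bp": [1, 2]})
        g = GenotypeMatrix(dos, np.array(["i1", "i2"]), mm)
        G = vanraden_G(g)
        np.testing.assert_allclose(G.values, [[2.0, -2.0], [-2.0, 2.0]])

    def test_fully_heterozygous_individual_zero_diagonal(self):
        dos = np.array([[1.0, 1.0], [0.0, 2.0], [2.0, 0.0]])
        mm = pd.DataFrame({"snp_id": ["a", "b"], "lg": [1, 1], "bp": [1, 2]})
        g = GenotypeMatrix(dos, np.array(["h", "x", "y"]), mm)
        G = vanraden_G(g)
        assert G.values[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_outbred_founder_mean_diagonal_near_one(self):
        d = SimDesign(
            n_founders_female=60,
            n_founders_male=60,
            family_sizes=(10,),
            n_lg=3,
            snps_per_lg=120,
            ld_decay_bp=0.0,
            seed=21,
        )
        founders = simulate_founder_haplotypes(d)
        h = founders.all_design
        dos = (h[0::2] + h[1::2]).astype(float)
        mm = founders.marker_map
        g = drop_monomorphic(
            GenotypeMatrix(dos, np.array([f"f{i}" for i in range(len(dos))]), mm)
        )
        G = vanraden_G(g)
        assert abs(np.diag(G.values).mean() - 1.0) < 0.05

    def test_allele_label_swap_invariance(self, small_pop, rng):
        g = small_pop["genotypes"]
        G1 = vanraden_G(g)
        dos = g.dosages.copy()
        swap = rng.random(g.n_snps) < 0.5
        dos[:, swap] = 2.0 - dos[:, swap]
        G2 = vanraden_G(GenotypeMatrix(dos, g.ids, g.marker_map))
        np.testing.assert_allclose(G1.values, G2.values, atol=1e-10)

    def test_ones_vector_in_null_space(self, small_kinships):
        G = small_kinships["G"]
        np.testing.assert_allclose(
            G.values @ np.ones(G.n), np.zeros(G.n), atol=1e-8
        )

    def test_monomorphic_rejected(self):
        dos = np.array([[2.0], [2.0]])
        mm = pd.DataFrame({"snp_id": ["a"], "lg": [1], "bp": [1]})
        with pytest.raises(ValueError, match="monomorphic"):
            vanraden_G(GenotypeMatrix(dos, np.array(["i", "j"]), mm))


class TestBlend:
    def test_epsilon_zero_identity(self, small_kinships):
        G = small_kinships["G"]
        np.testing.assert_array_equal(blend(G, 0.0).values, G.values)

    def test_epsilon_one_rejected(self, small_kinships):
        with pytest.raises(ValueError):
            blend(small_kinships["G"], 1.0)

    def test_minimum_eigenvalue_bound(self, small_kinships):
        eps = 0.02
        Gb = blend(small_kinships["G"], eps)
        w = np.linalg.eigvalsh(Gb.values)
        assert w.min() >= eps - 1e-10


class TestPCA:
    def test_design_vs_contaminant_offspring_separate_on_pcs(self):
        d = SimDesign(
            family_sizes=(80, 80), n_lg=3, snps_per_lg=60, seed=17,
            contamination_rate=0.3,
        )
        g, ped, _, contaminated = simulate_population(d)
        gi = impute_missing(drop_monomorphic(g))
        n_founder = 6
        off = gi.subset_individuals(gi.ids[n_founder:])
        scores, ev = pca_genotypes(off, 2)
        grp = contaminated
        sep = abs(scores[grp].mean(axis=0) - scores[~grp].mean(axis=0))
        spread = scores.std(axis=0)
        assert (sep / spread).max() > 1.0  # contaminants break away

    def test_duplicate_individuals_identical_scores(self, small_pop):
        g = small_pop["genotypes"]
        dup = GenotypeMatrix(
            np.vstack([g.dosages, g.dosages[:1]]),
            np.append(g.ids, "copy_of_first"),
            g.marker_map,
        )
        scores, _ = pca_genotypes(dup, 3)
        np.testing.assert_allclose(scores[0], scores[-1], atol=1e-8)

    def test_explained_variance_monotone_and_bounded(self, small_pop):
        _, ev = pca_genotypes(small_pop["genotypes"], 5)
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() <= 1.0 + 1e-12

    def test_k_too_large_rejected(self, small_pop):
        with pytest.raises(ValueError):
            pca_genotypes(small_pop["genotypes"], 10**6)


class TestCompareAG:
    def test_self_correlation_one(self, small_kinships):
        A = small_kinships["A"]
        out = compare_A_G(A, A)
        assert out["element_correlation"] == pytest.approx(1.0)

    def test_negated_matrix_correlation_minus_one(self, small_kinships):
        A = small_kinships["A"]
        negA = KinshipMatrix(-A.values, A.ids, "pedigree_A")
        out = compare_A_G(A, negA)
        assert out["element_correlation"] == pytest.approx(-1.0)

    def test_contamination_lowers_A_G_agreement(self):
        """Pollen contamination breaks recorded pedigree relationships, so
        the A-G element correlation drops relative to a clean population."""
        corrs = {}
        for rate in (0.0, 0.2):
            d = SimDesign(
                family_sizes=(70, 60, 50), n_lg=17, snps_per_lg=147, seed=31,
                contamination_rate=rate,
            )
            g, ped, _, _ = simulate_population(d)
            gi = impute_missing(drop_monomorphic(g))
            A = pedigree_A(ped).subset(gi.ids)
            G = vanraden_G(gi)
            corrs[rate] = compare_A_G(A, G)["element_correlation"]
        assert corrs[0.0] > 0.8
        assert corrs[0.2] < corrs[0.0]
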