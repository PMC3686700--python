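"""Association-scan behavior: EMMAX vs exact oracle, thresholds, PC
selection, R2_LR contributions, joint fits, Q-Q diagnostics, permutations."""

import numpy as np
import pytest

from sibgwas import (
    GenotypeMatrix,
    emmax_scan,
    exact_scan,
    genomewide_threshold,
    joint_r2,
    pca_genotypes,
    per_test_alpha,
    qq_data,
    select_pcs_bic,
)
from sibgwas.genio import drop_monomorphic, impute_missing
from sibgwas.relatedness import blend, vanraden_G
from sibgwas.simdata import (
    SimDesign,
    TraitArchitecture,
    _nearest_snp,
    simulate_population,
)


class TestThresholdArithmetic:
    def test_study_numbers(self):
        assert genomewide_threshold(5e-7, 2500) == pytest.approx(0.00125)

    def test_single_test_identity(self):
        assert genomewide_threshold(0.01, 1) == pytest.approx(0.01)

    def test_inverse_round_trip(self):
        assert per_test_alpha(0.00125, 2500) == pytest.approx(5e-7)

    def test_invalid_product_flagged(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            genomewide_threshold(0.01, 500)


@pytest.fixture(scope="module")
def qtl_scan():
    """Population with one strong QTL, its EMMAX scan, and the pieces needed
    to re-derive it."""
    d = SimDesign(
        family_sizes=(80, 70, 60, 40), n_lg=4, snps_per_lg=50, seed=23
    )
    arch = TraitArchitecture(
        n_traits=1,
        qtl_positions=[[(3, 15_000_000)]],
        qtl_effects=[[1.0]],
        h2=[0.5],
        polygenic_share=[0.3],
    )
    g, ped, phen, _ = simulate_population(d, arch)
    gi = impute_missing(drop_monomorphic(g))
    K = blend(vanraden_G(gi), 0.01)
    y = phen.set_index("id")["trait1"].reindex(gi.ids).to_numpy(dtype=float)
    res = emmax_scan(y, K, gi, threshold=5e-7)
    qtl_idx = _nearest_snp(gi.marker_map, 3, 15_000_000)
    return {"g": gi, "K": K, "y": y, "scan": res, "qtl_idx": qtl_idx}


def test_duplicate_snp_identical_results(qtl_scan):
    g = qtl_scan["g"]
    dos = g.dosages.copy()
    dos[:, 1] = dos[:, 0]
    mm = g.marker_map.copy()
    gdup = GenotypeMatrix(dos, g.ids, mm)
    res = emmax_scan(qtl_scan["y"], qtl_scan["K"], gdup)
    t = res.table
    for col in ("effect", "se", "t", "p", "r2lr"):
        assert t.loc[0, col] == pytest.approx(t.loc[1, col], rel=1e-10)


def test_monomorphic_snp_gives_missing_not_failure(qtl_scan):
    g = qtl_scan["g"]
    dos = g.dosages.copy()
    dos[:, 4] = 2.0
    res = emmax_scan(qtl_scan["y"], qtl_scan["K"], GenotypeMatrix(dos, g.ids, g.marker_map))
    assert np.isnan(res.table.loc[4, "p"])
    assert not res.table.loc[4, "significant"]


def test_qtl_detected_and_has_largest_r2lr(qtl_scan):
    res = qtl_scan["scan"]
    j = qtl_scan["qtl_idx"]
    assert res.significant.shape[0] >= 1
    # largest contribution at (or in tight LD with) the causal marker
    top = int(np.nanargmax(res.table["r2lr"].to_numpy()))
    top_row = res.table.loc[top]
    causal_row = res.table.loc[j]
    assert top_row["lg"] == causal_row["lg"]
    assert abs(top_row["bp"] - causal_row["bp"]) <= 2_000_000


def test_r2lr_zero_for_null_snp_and_coding_invariance(qtl_scan):
    res = qtl_scan["scan"]
    t = res.table
    weakest = t.loc[t["t"].abs().idxmin()]
    assert abs(weakest["r2lr"]) < 0.01
    # allele-label swap: flip dosage coding of the top SNP
    g = qtl_scan["g"]
    j = int(np.nanargmax(t["r2lr"].to_numpy()))
    dos = g.dosages.copy()
    dos[:, j] = 2.0 - dos[:, j]
    res2 = emmax_scan(qtl_scan["y"], qtl_scan["K"], GenotypeMatrix(dos, g.ids, g.marker_map))
    assert res2.table.loc[j, "r2lr"] == pytest.approx(t.loc[j, "r2lr"], rel=1e-8)
    assert res2.table.loc[j, "effect"] == pytest.approx(-t.loc[j, "effect"], rel=1e-8)


def test_emmax_close_to_exact_per_snp_reml(qtl_scan):
    """EMMAX approximation vs per-SNP REML re-estimation on a subset."""
    g = qtl_scan["g"]
    sub = g.subset_snps(np.arange(60))
    res_e = emmax_scan(qtl_scan["y"], qtl_scan["K"], sub)
    res_x = exact_scan(qtl_scan["y"], qtl_scan["K"], sub)
    d = np.abs(res_e.table["neglog10p"] - res_x.table["neglog10p"])
    assert np.nanmax(d) < 0.05


def test_structure_correction_changes_little(qtl_scan):
    """'Q+K' vs 'K': adding PC covariates barely moves SNP effects when the
    kinship already captures the structure."""
    g, K, y = qtl_scan["g"], qtl_scan["K"], qtl_scan["y"]
    pcs, _ = pca_genotypes(g, 2)
    r0 = emmax_scan(y, K, g, n_pcs=0)
    r2 = emmax_scan(y, K, g, n_pcs=2, pcs=pcs)
    ok = np.isfinite(r0.table["effect"]) & np.isfinite(r2.table["effect"])
    corr = np.corrcoef(r0.table["effect"][ok], r2.table["effect"][ok])[0, 1]
    assert corr > 0.95


def test_permuted_phenotype_loses_genomewide_hits(qtl_scan, rng):
    g, K, y = qtl_scan["g"], qtl_scan["K"], qtl_scan["y"]
    assert qtl_scan["scan"].significant.shape[0] >= 1
    losses = 0
    perms = 8
    for _ in range(perms):
        res = emmax_scan(rng.permutation(y), K, g, threshold=5e-7)
        losses += res.significant.shape[0] == 0
    assert losses == perms


class TestSelectPCs:
    def test_max_pcs_zero_trivial(self, small_kinships, trait_vectors):
        y1, _ = trait_vectors
        assert select_pcs_bic(y1, small_kinships["G_blend"], None, 0) == 0

    def test_structured_trait_selects_pcs(self, small_pop, small_kinships):
        g = small_pop["genotypes"]
        pcs, _ = pca_genotypes(g, 4)
        rng = np.random.default_rng(3)
        y = 2.0 * pcs[:, 0] / pcs[:, 0].std() + 0.5 * rng.normal(size=g.n_individuals)
        k = select_pcs_bic(y, small_kinships["G_blend"], pcs, 4)
        assert k >= 1

    def test_unstructured_trait_selects_none(self, small_pop, small_kinships):
        g = small_pop["genotypes"]
        pcs, _ = pca_genotypes(g, 4)
        rng = np.random.default_rng(9)
        chosen = [
            select_pcs_bic(rng.normal(size=g.n_individuals),
                           small_kinships["G_blend"], pcs, 4)
            for _ in range(10)
        ]
        assert sum(k == 0 for k in chosen) >= 9

    def test_max_pcs_bound(self, small_kinships, trait_vectors):
        y1, _ = trait_vectors
        with pytest.raises(ValueError):
            select_pcs_bic(y1, small_kinships["G_blend"], None, len(y1))


class TestJointR2:
    def test_single_significant_snp_equals_its_contribution(self, qtl_scan):
        res = qtl_scan["scan"]
        sig = res.significant
        if len(sig) > 1:
            # force a single survivor via the 5 Mb window rule first
            pass
        out = joint_r2(qtl_scan["y"], qtl_scan["K"], qtl_scan["g"], res)
        kept = out["kept_snps"]
        if len(kept) == 1:
            row = res.table[res.table["snp_id"] == kept[0]].iloc[0]
            assert out["joint_r2lr"] == pytest.approx(row["r2lr"], rel=1e-8)

    def test_window_pruning_keeps_one_per_cluster(self, qtl_scan):
        res = qtl_scan["scan"]
        out = joint_r2(qtl_scan["y"], qtl_scan["K"], qtl_scan["g"], res,
                       window_bp=5_000_000)
        kept = res.table[res.table["snp_id"].isin(out["kept_snps"])]
        for lg, grp in kept.groupby("lg"):
            bp = np.sort(grp["bp"].to_numpy())
            assert np.all(np.diff(bp) > 5_000_000)

    def test_joint_at_least_best_single(self, qtl_scan):
        res = qtl_scan["scan"]
        out = joint_r2(qtl_scan["y"], qtl_scan["K"], qtl_scan["g"], res)
        best = res.table.loc[res.table["significant"], "r2lr"].max()
        assert out["joint_r2lr"] >= best - 1e-10

    def test_no_significant_returns_zero_with_note(self, qtl_scan, rng):
        y = rng.normal(size=len(qtl_scan["y"]))
        res = emmax_scan(y, qtl_scan["K"], qtl_scan["g"], threshold=5e-7)
        out = joint_r2(y, qtl_scan["K"], qtl_scan["g"], res)
        assert out["joint_r2lr"] == 0.0
        assert "note" in out


class TestQQ:
    def test_uniform_pvalues_lambda_near_one(self, qtl_scan, rng):
        """Genuinely uniform p-values calibrate lambda_GC to ~1; a null scan
        over LD-correlated SNPs stays in a broad band around 1."""
        res = qtl_scan["scan"]
        big = res.table.iloc[np.zeros(2500, dtype=int)].assign(
            p=rng.uniform(1e-12, 1, 2500)
        )
        uni = type(res)(table=big, n=res.n, n_pcs=0, delta=res.delta,
                        threshold=res.threshold)
        assert abs(qq_data(uni)["lambda_gc"] - 1.0) < 0.1
        null_scan = emmax_scan(
            rng.normal(size=len(qtl_scan["y"])), qtl_scan["K"], qtl_scan["g"]
        )
        assert 0.5 < qq_data(null_scan)["lambda_gc"] < 1.5

    def test_observed_curve_sorted(self, qtl_scan):
        qq = qq_data(qtl_scan["scan"])
        assert np.all(np.diff(qq["observed"]) >= 0)
        assert len(qq["observed"]) == len(qq["expected"])

    def test_all_p_one_flatlines(self, qtl_scan):
        res = qtl_scan["scan"]
        res2 = type(res)(
            table=res.table.assign(p=1.0), n=res.n, n_pcs=0, delta=res.delta,
            threshold=res.threshold,
        )
        qq = qq_data(res2)
        assert np.allclose(qq["observed"], 0.0)


def test_power_increases_with_qtl_variance_share():
    """-log10 p at the causal SNP grows with its variance share."""
    d = SimDesign(family_sizes=(150, 150, 150), n_lg=3, snps_per_lg=50, seed=41)
    g, ped, _, _ = simulate_population(d)
    gi = impute_missing(drop_monomorphic(g))
    K = blend(vanraden_G(gi), 0.01)
    j = _nearest_snp(gi.marker_map, 2, 15_000_000)
    neglogs = []
    for share_seed, qtl_share in [(1, 0.005), (2, 0.02), (3, 0.10)]:
        rng = np.random.default_rng(share_seed)
        snp = gi.dosages[:, j]
        snpc = snp - snp.mean()
        gval = snpc * np.sqrt(qtl_share / np.var(snpc))
        y = gval + rng.normal(scale=np.sqrt(1 - qtl_share), size=len(snp))
        res = emmax_scan(y, K, gi)
        neglogs.append(res.table.loc[j, "neglog10p"])
    assert neglogs[0] < neglogs[1] < neglogs[2]
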