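"""Per-miRNA and miRNome DC enrichment against hand arithmetic and
exhaustive relabeling oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from mirdc import (
    DCPair,
    DegenerateScoreError,
    GeneSet,
    GeneSetCollection,
    SyntheticTruth,
    enrich_collection_dc,
    generate_collection,
    generate_null_study,
    generate_planted_study,
    member_indices,
    mirna_pathway_z,
    mirnome_pathway_z,
    study_from_arrays,
)


class TestMirnaPathwayZ:
    def test_members_at_column_mean_give_zero(self):
        s = np.array([[1.0], [3.0], [2.0], [2.0]])
        assert mirna_pathway_z(s, np.array([2, 3]), 0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        # column (1,2,3,4), members (3,4): sigma = population sd = sqrt(1.25)
        s = np.array([[1.0], [2.0], [3.0], [4.0]])
        expected = math.sqrt(2 * 3 / 2) * (3.5 - 2.5) / math.sqrt(1.25)
        assert mirna_pathway_z(s, np.array([2, 3]), 0) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_coupling_change(self):
        """A larger correlation change yields a larger median Z."""
        medians = []
        for c in (0.3, 0.8):
            zs = []
            for seed in range(5):
                universe = [f"g{i:04d}" for i in range(100)]
                coll = generate_collection(2, (12, 12), universe, seed=6)
                truth = SyntheticTruth(
                    dc_pairs=(DCPair(coll.names[0], "mir-0000", 0.0, c),),
                    seed=400 + seed,
                )
                study, _ = generate_planted_study(100, 5, 12, truth, coll)
                from mirdc import dc_score_matrix

                s = dc_score_matrix(study).s
                idx = member_indices(coll[coll.names[0]], study.gene_ids)
                zs.append(mirna_pathway_z(s, idx, 0))
            medians.append(np.median(zs))
        assert medians[1] > medians[0]


class TestMirnomePathwayZ:
    def test_reduces_to_per_mirna_at_m1(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            s = rng.exponential(size=(rng.integers(5, 40), 1))
            idx = np.arange(rng.integers(1, s.shape[0] - 1))
            assert mirnome_pathway_z(s, idx) == pytest.approx(
                mirna_pathway_z(s, idx, 0), abs=1e-12
            )

    def test_member_block_at_global_mean_gives_zero(self):
        s = np.array([[2.0, 2.0], [1.0, 3.0], [4.0, 0.0]])
        assert mirnome_pathway_z(s, np.array([0])) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_3x2(self):
        s = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        idx = np.array([1])
        K, G, M = 1, 3, 2
        mu = s.mean()
        sigma = s.std(ddof=0)
        expected = math.sqrt(K * M * (G * M - 1) / (M * (G - K))) * (3.5 - mu) / sigma
        assert mirnome_pathway_z(s, idx) == pytest.approx(expected, abs=1e-12)

    def test_prefactor_identity_with_km_substitution(self):
        """The miRNome prefactor equals the per-miRNA one with K->KM, G->GM."""
        for K, G, M in [(3, 10, 4), (7, 50, 2), (1, 5, 9)]:
            a = math.sqrt(K * M * (G * M - 1) / (M * (G - K)))
            b = math.sqrt((K * M) * (G * M - 1) / (G * M - K * M))
            assert a == pytest.approx(b, abs=1e-12)


def naive_dc_mirnome_p(study, gene_set):
    """Exhaustive within-pair relabeling with plain per-pair spearmanr calls."""
    N = study.N
    midx = member_indices(gene_set, study.gene_ids)

    def score(gn, gd, mn, md):
        G, M = gn.shape[0], mn.shape[0]
        s = np.empty((G, M))
        for i in range(G):
            for j in range(M):
                rn = stats.spearmanr(gn[i], mn[j]).statistic
                rd = stats.spearmanr(gd[i], md[j]).statistic
                f = math.sqrt((N - 3) / 1.06)
                s[i, j] = abs(f * math.atanh(np.clip(rn, -1 + 1e-7, 1 - 1e-7))
                              - f * math.atanh(np.clip(rd, -1 + 1e-7, 1 - 1e-7)))
        K = midx.size
        mu, sigma = s.mean(), s.std(ddof=0)
        pref = math.sqrt(K * M * (G * M - 1) / (M * (G - K)))
        return pref * (s[midx].mean() - mu) / sigma

    g, m = study.genes, study.mirnas
    z_obs = score(g.normal, g.diseased, m.normal, m.diseased)
    count = total = 0
    for flips in itertools.product([False, True], repeat=N):
        w = np.array(flips)
        z = score(np.where(w, g.diseased, g.normal), np.where(w, g.normal, g.diseased),
                  np.where(w, m.diseased, m.normal), np.where(w, m.normal, m.diseased))
        count += z >= z_obs - 1e-9
        total += 1
    return count / total


class TestDCPermutation:
    def test_identical_conditions_degenerate(self):
        X = np.random.default_rng(2).normal(size=(8, 5))
        Y = np.random.default_rng(3).normal(size=(3, 5))
        study = study_from_arrays(X, X.copy(), Y, Y.copy())
        coll = GeneSetCollection(sets=(GeneSet("S", "", frozenset(study.gene_ids[:3])),))
        with pytest.raises(DegenerateScoreError):
            enrich_collection_dc(study, coll, mode="mirnome", B=5, seed=0)

    def test_exhaustive_matches_naive_enumeration(self):
        study = generate_null_study(G=8, M=2, N=4, seed=29)
        gs = GeneSet("S", "", frozenset(study.gene_ids[:3]))
        coll = GeneSetCollection(sets=(gs,))
        res = enrich_collection_dc(study, coll, mode="mirnome", exhaustive=True)
        assert res.iloc[0]["p_perm"] == pytest.approx(naive_dc_mirnome_p(study, gs),
                                                      abs=1e-12)

    def test_condition_swap_invariance(self, null_study, small_collection):
        fwd = enrich_collection_dc(null_study, small_collection, mode="mirna",
                                   B=30, seed=5)
        rev = enrich_collection_dc(null_study.swap_conditions(), small_collection,
                                   mode="mirna", B=30, seed=5)
        np.testing.assert_allclose(fwd["Z"], rev["Z"], atol=1e-12)
        np.testing.assert_allclose(fwd["p_perm"], rev["p_perm"], atol=1e-12)

    def test_rank_invariance_to_feature_shifts(self, null_study, small_collection):
        base = enrich_collection_dc(null_study, small_collection, mode="mirnome",
                                    B=25, seed=6)
        shifted = study_from_arrays(
            null_study.genes.normal + np.arange(null_study.G)[:, None] * 7.5,
            null_study.genes.diseased + np.arange(null_study.G)[:, None] * 7.5,
            null_study.mirnas.normal + 3.0,
            null_study.mirnas.diseased + 3.0,
            gene_ids=null_study.gene_ids,
            mirna_ids=null_study.mirna_ids,
        )
        res = enrich_collection_dc(shifted, small_collection, mode="mirnome",
                                   B=25, seed=6)
        np.testing.assert_array_equal(base["Z"], res["Z"])
        np.testing.assert_array_equal(base["p_perm"], res["p_perm"])

    def test_planted_pair_recovered(self):
        universe = [f"g{i:04d}" for i in range(300)]
        coll = generate_collection(4, (20, 20), universe, seed=8)
        truth = SyntheticTruth(
            dc_pairs=(DCPair(coll.names[0], "mir-0002", 0.0, 0.8),), seed=51,
        )
        study, _ = generate_planted_study(300, 8, 15, truth, coll)
        res = enrich_collection_dc(study, coll, mode="mirna", B=100, seed=9)
        row = res[(res["set_name"] == coll.names[0]) & (res["mirna_id"] == "mir-0002")]
        assert row.iloc[0]["p_perm"] == res["p_perm"].min()
        assert row.iloc[0]["p_perm"] == pytest.approx(1 / 101)

    def test_bh_families(self, null_study, small_collection):
        per = enrich_collection_dc(null_study, small_collection, mode="mirna",
                                   B=20, seed=3)
        assert per.attrs["bh_family"] == "set x miRNA pairs"
        assert len(per) == len(small_collection) * null_study.M
        ome = enrich_collection_dc(null_study, small_collection, mode="mirnome",
                                   B=20, seed=3)
        assert len(ome) == len(small_collection)
        assert (ome["mirna_id"] == "ALL").all()


def test_attach_dc_mirnas(null_study, small_collection):
    from mirdc import attach_dc_mirnas

    per = enrich_collection_dc(null_study, small_collection, mode="mirna", B=20, seed=1)
    ome = enrich_collection_dc(null_study, small_collection, mode="mirnome", B=20, seed=1)
    out = attach_dc_mirnas(ome, per, threshold=0.5)
    for _, row in out.iterrows():
        expected = sorted(per[(per["set_name"] == row["set_name"])
                              & (per["p_perm"] < 0.5)]["mirna_id"])
        assert row["dc_mirnas"] == ";".join(expected)
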