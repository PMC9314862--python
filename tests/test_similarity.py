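import itertools

import numpy as np
import pytest

from bganmda.io_formats import EntityIndex, SequenceSet
from bganmda.similarity import (
    DegenerateInputError,
    SimilarityMatrix,
    SimilarityParams,
    build_pair_features,
    dag_semantic_values,
    disease_semantic_similarity,
    disease_similarity_network,
    functional_similarity,
    gip_kernel,
    integrate_similarity,
    mirna_similarity_network,
    sequence_similarity,
    weighted_edit_distance,
)


def edit_oracle(s1, s2, sub, ind):
    """Exhaustive recursive search over all edit scripts (tiny strings only)."""
    if not s1:
        return len(s2) * ind
    if not s2:
        return len(s1) * ind
    return min(
        edit_oracle(s1[1:], s2[1:], sub, ind) + (0 if s1[0] == s2[0] else sub),
        edit_oracle(s1[1:], s2, sub, ind) + ind,
        edit_oracle(s1, s2[1:], sub, ind) + ind,
    )


class TestWeightedEditDistance:
    @pytest.mark.parametrize("s1,s2,sub,ind,expected", [
        ("ACGU", "ACGU", 2, 1, 0),
        ("ACGU", "", 2, 1, 4),
        ("", "", 2, 1, 0),
        ("ACGU", "AGGU", 2, 1, 2),   # one substitution beats any indel script
    ])
    def test_known_values(self, s1, s2, sub, ind, expected):
        assert weighted_edit_distance(s1, s2, sub, ind) == expected

    def test_matches_exhaustive_oracle_on_all_short_pairs(self):
        strings = ["".join(t) for n in range(5)
                   for t in itertools.product("AC", repeat=n)]
        for s1 in strings:
            for s2 in strings:
                assert weighted_edit_distance(s1, s2, 2, 1) == edit_oracle(s1, s2, 2, 1)

    def test_agrees_with_edlib_at_unit_costs(self):
        edlib = pytest.importorskip("edlib")
        rng = np.random.default_rng(11)
        nucs = np.array(list("ACGU"))
        for _ in range(40):
            s1 = "".join(rng.choice(nucs, size=rng.integers(1, 25)))
            s2 = "".join(rng.choice(nucs, size=rng.integers(1, 25)))
            expected = edlib.align(s1, s2, task="distance")["editDistance"]
            assert weighted_edit_distance(s1, s2, 1, 1) == expected

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(5)
        nucs = np.array(list("ACGU"))
        seqs = ["".join(rng.choice(nucs, size=rng.integers(0, 10))) for _ in range(12)]
        for a, b, c in itertools.combinations(seqs, 3):
            dab = weighted_edit_distance(a, b)
            assert dab == weighted_edit_distance(b, a)
            assert dab <= weighted_edit_distance(a, c) + weighted_edit_distance(c, b)


class TestSequenceSimilarity:
    def test_three_sequence_fixture(self):
        # raw scores 1 - d/(len_i + len_j): d(ACGU,AGGU)=2 -> 0.75,
        # d(ACGU,UUUU)=6 -> 0.25, d(AGGU,UUUU)=6 -> 0.25; min-max rescale
        # maps 0.75 -> 1 and 0.25 -> 0.
        idx = EntityIndex(["m1", "m2", "m3"], "mirna")
        seqs = SequenceSet({"m1": "ACGU", "m2": "AGGU", "m3": "UUUU"})
        mss = sequence_similarity(seqs, idx)
        expected = np.array([
            [1.0, 1.0, 0.0],
            [1.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
        ])
        np.testing.assert_allclose(mss.values, expected, atol=1e-12)

    def test_offdiagonal_minmax_property(self, default_synthetic):
        bm, seqs, _, _ = default_synthetic
        mss = sequence_similarity(seqs, bm.mirna_index)
        off = mss.values[~np.eye(len(bm.mirna_index), dtype=bool)]
        assert off.min() == pytest.approx(0.0)
        assert off.max() == pytest.approx(1.0)

    def test_missing_sequence_rows_zero(self):
        idx = EntityIndex(["m1", "m2", "m3"], "mirna")
        seqs = SequenceSet({"m1": "ACGU", "m2": "AGGU"})
        mss = sequence_similarity(seqs, idx)
        assert mss.values[2, 0] == 0.0 and mss.values[0, 2] == 0.0
        assert mss.values[2, 2] == 1.0

    def test_all_missing_is_degenerate(self):
        idx = EntityIndex(["m1"], "mirna")
        with pytest.raises(DegenerateInputError):
            sequence_similarity(SequenceSet({}), idx)


class TestSemanticValues:
    def test_decay_model_on_two_node_chain(self, chain_forest):
        table = dag_semantic_values(chain_forest, model=1)
        assert table.contributions["c"] == {"c": 1.0, "r": 0.5}
        assert table.sv["c"] == pytest.approx(1.5)
        assert table.sv["r"] == pytest.approx(1.0)

    def test_self_contribution_is_one(self, three_chain_forest):
        table = dag_semantic_values(three_chain_forest, model=1)
        for d in ("r", "a", "b"):
            assert table.contributions[d][d] == 1.0

    def test_information_content_zero_when_term_in_every_dag(self):
        import networkx as nx
        from bganmda.io_formats import DiseaseDagForest
        g1, g2 = nx.DiGraph(), nx.DiGraph()
        g1.add_edge("x", "y")
        g2.add_edge("y", "x")
        forest = DiseaseDagForest({"g1": g1, "g2": g2})
        table = dag_semantic_values(forest, model=2)
        # both diseases appear in both DAGs of a 2-disease forest
        assert table.contributions["x"]["x"] == pytest.approx(0.0)

    def test_three_chain_decay_values(self, three_chain_forest):
        table = dag_semantic_values(three_chain_forest, model=1)
        assert table.contributions["b"] == pytest.approx({"b": 1.0, "a": 0.5, "r": 0.25})
        assert table.sv["b"] == pytest.approx(1.75)


class TestDiseaseSemanticSimilarity:
    def test_chain_similarity_hand_value(self, chain_forest):
        idx = EntityIndex(["r", "c"], "disease")
        dss1 = disease_semantic_similarity(chain_forest, idx, model=1)
        # shared ancestor r: (C_c(r) + C_r(r)) / (SV(c) + SV(r)) = 1.5 / 2.5
        assert dss1.values[idx.position("c"), idx.position("r")] == pytest.approx(0.6, abs=1e-9)
        assert dss1.values[0, 0] == 1.0

    def test_three_chain_hand_matrix(self, three_chain_forest):
        idx = EntityIndex(["r", "a", "b"], "disease")
        dss1 = disease_semantic_similarity(three_chain_forest, idx, model=1)
        dss2 = disease_semantic_similarity(three_chain_forest, idx, model=2)
        dsn = disease_similarity_network(dss1, dss2)
        # model 1: 0.6, 5/11, 9/13; model 2 (all C2 = ln 3): 2/3, 1/2, 4/5
        np.testing.assert_allclose(
            [dss1.values[0, 1], dss1.values[0, 2], dss1.values[1, 2]],
            [0.6, 5 / 11, 9 / 13], atol=1e-12)
        np.testing.assert_allclose(
            [dss2.values[0, 1], dss2.values[0, 2], dss2.values[1, 2]],
            [2 / 3, 1 / 2, 4 / 5], atol=1e-12)
        np.testing.assert_allclose(
            [dsn.values[0, 1], dsn.values[0, 2], dsn.values[1, 2]],
            [(0.6 + 2 / 3) / 2, (5 / 11 + 0.5) / 2, (9 / 13 + 0.8) / 2], atol=1e-12)

    def test_disjoint_dags_give_zero(self):
        import networkx as nx
        from bganmda.io_formats import DiseaseDagForest
        g1, g2 = nx.DiGraph(), nx.DiGraph()
        g1.add_edge("r1", "c1")
        g2.add_edge("r2", "c2")
        forest = DiseaseDagForest({"g1": g1, "g2": g2})
        idx = EntityIndex(["c1", "c2"], "disease")
        for model in (1, 2):
            dss = disease_semantic_similarity(forest, idx, model=model)
            assert dss.values[0, 1] == 0.0

    def test_disease_outside_forest_zero_row(self, chain_forest):
        idx = EntityIndex(["r", "c", "orphan"], "disease")
        dss = disease_semantic_similarity(chain_forest, idx, model=1)
        k = idx.position("orphan")
        assert dss.values[k].sum() == 1.0  # only the diagonal


class TestDiseaseNetwork:
    def test_mean_is_idempotent_on_equal_inputs(self, toy_dsn):
        out = disease_similarity_network(toy_dsn, toy_dsn)
        np.testing.assert_allclose(out.values, toy_dsn.values)

    def test_elementwise_mean(self, toy_dsn):
        other = SimilarityMatrix(np.eye(3), toy_dsn.index, "DSS2")
        out = disease_similarity_network(toy_dsn, other)
        assert out.values[0, 1] == pytest.approx(0.3)

    def test_index_mismatch_raises(self, toy_dsn):
        other = SimilarityMatrix(np.eye(2), EntityIndex(["a", "b"], "disease"), "DSS2")
        with pytest.raises(ValueError):
            disease_similarity_network(toy_dsn, other)


class TestFunctionalSimilarity:
    # D(m1) = {d1, d2}, D(m2) = {d2, d3} over the hand DSN:
    # intersection mode: shared disease d2 has max-sim 1 to both sets -> 2/4
    # union_max mode: (0.6 + 1) + (1 + 0.4) -> 3/4
    @pytest.mark.parametrize("mode,expected", [
        ("intersection", 0.5),
        ("union_max", 0.75),
    ])
    def test_hand_value_per_mode(self, toy_bm, toy_dsn, mode, expected):
        params = SimilarityParams(functional_mode=mode)
        mfs = functional_similarity(toy_bm, toy_dsn, params)
        assert mfs.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_equal_nonempty_sets_give_one(self, toy_dsn):
        from bganmda.io_formats import AssociationMatrix
        bm = AssociationMatrix(
            np.array([[1, 1], [1, 1], [0, 0]]),
            toy_dsn.index, EntityIndex(["m1", "m2"], "mirna"))
        for mode in ("intersection", "union_max"):
            mfs = functional_similarity(bm, toy_dsn, SimilarityParams(functional_mode=mode))
            assert mfs.values[0, 1] == pytest.approx(1.0)

    def test_disjoint_sets_zero_under_intersection(self, toy_dsn):
        from bganmda.io_formats import AssociationMatrix
        bm = AssociationMatrix(
            np.array([[1, 0], [0, 0], [0, 1]]),
            toy_dsn.index, EntityIndex(["m1", "m2"], "mirna"))
        mfs = functional_similarity(bm, toy_dsn, SimilarityParams(functional_mode="intersection"))
        assert mfs.values[0, 1] == 0.0

    def test_empty_disease_set_row_zero_except_diagonal(self, toy_dsn):
        from bganmda.io_formats import AssociationMatrix
        bm = AssociationMatrix(
            np.array([[1, 0], [1, 0], [0, 0]]),
            toy_dsn.index, EntityIndex(["m1", "m2"], "mirna"))
        mfs = functional_similarity(bm, toy_dsn)
        assert mfs.values[1, 0] == 0.0
        assert mfs.values[1, 1] == 1.0


class TestMirnaNetwork:
    def test_alpha_extremes_select_single_matrix(self, toy_dsn):
        idx = EntityIndex(["m1", "m2"], "mirna")
        mfs = SimilarityMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), idx, "MFS")
        mss = SimilarityMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]), idx, "MSS")
        np.testing.assert_allclose(mirna_similarity_network(mfs, mss, 1.0).values, mfs.values)
        np.testing.assert_allclose(mirna_similarity_network(mfs, mss, 0.0).values, mss.values)

    def test_default_mixing_weight(self):
        idx = EntityIndex(["m1", "m2"], "mirna")
        mfs = SimilarityMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), idx, "MFS")
        mss = SimilarityMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]), idx, "MSS")
        msn = mirna_similarity_network(mfs, mss, 0.6)
        assert msn.values[0, 1] == pytest.approx(0.7)

    def test_alpha_out_of_range(self):
        idx = EntityIndex(["m1"], "mirna")
        m = SimilarityMatrix(np.eye(1), idx, "MFS")
        with pytest.raises(ValueError):
            mirna_similarity_network(m, m, 1.5)


class TestGipKernel:
    def test_orthogonal_unit_profiles(self):
        from bganmda.io_formats import AssociationMatrix
        bm = AssociationMatrix(
            np.array([[1, 0], [0, 1]]),
            EntityIndex(["d1", "d2"], "disease"), EntityIndex(["m1", "m2"], "mirna"))
        for norm in ("squared", "linear"):
            k = gip_kernel(bm, "mirna", SimilarityParams(gip_norm=norm))
            assert k.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-9)
            assert k.values[0, 0] == 1.0

    def test_doubling_bandwidth_squares_entries(self, default_synthetic):
        bm, *_ = default_synthetic
        k1 = gip_kernel(bm, "disease", SimilarityParams(lambda_prime=1.0))
        k2 = gip_kernel(bm, "disease", SimilarityParams(lambda_prime=2.0))
        np.testing.assert_allclose(k2.values, k1.values**2, atol=1e-12)

    def test_invariant_to_permutation_of_other_axis(self, default_synthetic):
        from bganmda.io_formats import AssociationMatrix
        bm, *_ = default_synthetic
        rng = np.random.default_rng(0)
        perm = rng.permutation(bm.nd)
        shuffled = AssociationMatrix(bm.bm[perm], bm.disease_index, bm.mirna_index)
        k1 = gip_kernel(bm, "mirna")
        k2 = gip_kernel(shuffled, "mirna")
        np.testing.assert_allclose(k1.values, k2.values, atol=1e-12)

    def test_all_zero_matrix_degenerate(self):
        from bganmda.io_formats import AssociationMatrix
        bm = AssociationMatrix(
            np.zeros((2, 2), dtype=int),
            EntityIndex(["d1", "d2"], "disease"), EntityIndex(["m1", "m2"], "mirna"))
        with pytest.raises(DegenerateInputError):
            gip_kernel(bm, "mirna")


class TestIntegration:
    def _random_pair(self, rng, n, kind, index):
        v = rng.random((n, n))
        v = (v + v.T) / 2
        v[rng.random((n, n)) < 0.4] = 0.0  # sparsify
        v = np.minimum(v, v.T)
        np.fill_diagonal(v, 1.0)
        return SimilarityMatrix(v, index, kind)

    def test_matches_elementwise_oracle_on_random_inputs(self):
        rng = np.random.default_rng(42)
        n = 8
        midx = EntityIndex([f"m{i}" for i in range(n)], "mirna")
        didx = EntityIndex([f"d{i}" for i in range(n)], "disease")
        for _ in range(10):
            msn = self._random_pair(rng, n, "MSN", midx)
            mgs = self._random_pair(rng, n, "MGS", midx)
            dsn = self._random_pair(rng, n, "DSN", didx)
            dgs = self._random_pair(rng, n, "DGS", didx)
            ms, ds = integrate_similarity(msn, mgs, dsn, dgs)
            for out, net, gip in ((ms, msn, mgs), (ds, dsn, dgs)):
                for i in range(n):
                    for j in range(n):
                        if i == j:
                            assert out.values[i, j] == 1.0
                        elif net.values[i, j] > 0:
                            assert out.values[i, j] == net.values[i, j]
                        else:
                            assert out.values[i, j] == gip.values[i, j]

    def test_network_value_takes_precedence(self, toy_dsn):
        idx = toy_dsn.index
        gip = SimilarityMatrix(np.full((3, 3), 0.9) + 0.1 * np.eye(3), idx, "DGS")
        zero = SimilarityMatrix(np.eye(3), idx, "DSN")
        _, ds = integrate_similarity(
            SimilarityMatrix(np.eye(3), EntityIndex(["a", "b", "c"], "mirna"), "MSN"),
            SimilarityMatrix(np.eye(3), EntityIndex(["a", "b", "c"], "mirna"), "MGS"),
            toy_dsn, gip)
        assert ds.values[0, 1] == toy_dsn.values[0, 1]  # 0.6 kept, not 0.9
        _, ds0 = integrate_similarity(
            SimilarityMatrix(np.eye(3), EntityIndex(["a", "b", "c"], "mirna"), "MSN"),
            SimilarityMatrix(np.eye(3), EntityIndex(["a", "b", "c"], "mirna"), "MGS"),
            zero, gip)
        assert ds0.values[0, 1] == 0.9  # fallback branch


class TestPairFeatures:
    def test_vector_layout_and_length(self, toy_bm, toy_dsn):
        midx = toy_bm.mirna_index
        ms = SimilarityMatrix(np.array([[1.0, 0.3], [0.3, 1.0]]), midx, "MS")
        feats = build_pair_features(ms, toy_dsn, toy_bm)
        assert feats.n_features == 5
        assert len(feats) == 6
        v = feats.vector("m1", "d2")
        np.testing.assert_allclose(v[:2], ms.values[0])
        # position nm + k holds DS(d2, d_k)
        np.testing.assert_allclose(v[2:], toy_dsn.values[1])

    def test_labels_follow_association_matrix(self, toy_bm, toy_dsn):
        ms = SimilarityMatrix(np.eye(2), toy_bm.mirna_index, "MS")
        feats = build_pair_features(ms, toy_dsn, toy_bm)
        _, y = feats.matrix([(0, 0), (1, 0), (0, 2)])
        assert y.tolist() == [1, 0, 0]

    def test_unknown_entity_raises(self, toy_bm, toy_dsn):
        ms = SimilarityMatrix(np.eye(2), toy_bm.mirna_index, "MS")
        feats = build_pair_features(ms, toy_dsn, toy_bm)
        with pytest.raises(KeyError):
            feats.vector("nonexistent", "d1")


class TestMatrixInvariants:
    """Symmetry, unit diagonal and [0,1] bounds across the whole pipeline."""

    @pytest.mark.parametrize("seed", range(8))
    def test_all_similarity_kinds_well_formed(self, seed):
        from bganmda.evaluation import Dataset
        from bganmda.synthetic_data import SyntheticSpec, gen_dataset
        bm, seqs, forest, _ = gen_dataset(
            SyntheticSpec(nm=14, nd=10, latent_rank=2, density=0.15, n_dags=2, seed=seed))
        params = SimilarityParams()
        ds_set = Dataset(bm, seqs, forest)
        mss, dsn = ds_set.base_similarities(params)
        mfs = functional_similarity(bm, dsn, params)
        msn = mirna_similarity_network(mfs, mss, params.alpha)
        mgs = gip_kernel(bm, "mirna", params)
        dgs = gip_kernel(bm, "disease", params)
        ms, ds = integrate_similarity(msn, mgs, dsn, dgs)
        for mat in (mss, mfs, msn, mgs, dsn, dgs, ms, ds):
            mat.check(atol=1e-9)
        assert mgs.values.min() > 0.0 and dgs.values.min() > 0.0
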