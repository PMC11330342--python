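"""Similarity-measure tests against independently coded brute-force oracles."""

import numpy as np
import pytest

from miloc.datatypes import (
    AssociationMatrix,
    DiseaseDAG,
    EntityIndex,
    SimilarityMatrix,
    ValidationError,
)
from miloc.similarity import (
    AlignmentScoring,
    binarize_network,
    disease_semantic_similarity,
    fuse_with_gip,
    gip_kernel,
    mirna_functional_similarity,
    semantic_values,
    sequence_similarity,
    smith_waterman_score,
)

# ---------------------------------------------------------------- oracles


def gip_oracle(A):
    """Element-by-element GIP kernel evaluation."""
    A = np.asarray(A, dtype=float)
    n = len(A)
    lam = n / sum(np.dot(A[k], A[k]) for k in range(n))
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d = A[i] - A[j]
            out[i, j] = np.exp(-lam * np.dot(d, d))
    return out


def sw_oracle(a, b, match, mismatch, gap):
    """Textbook local-alignment DP with linear gaps."""
    m, n = len(a), len(b)
    H = np.zeros((m + 1, n + 1))
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap)
            best = max(best, H[i, j])
    return best


def semantic_oracle(edges, delta, disease):
    """Recursive contribution/semantic-value evaluation over explicit dicts."""
    parents = {}
    for u, v in edges:
        parents.setdefault(v, set()).add(u)

    closure = {disease}
    frontier = [disease]
    while frontier:
        node = frontier.pop()
        for p in parents.get(node, ()):
            if p not in closure:
                closure.add(p)
                frontier.append(p)

    children = {}
    for u, v in edges:
        children.setdefault(u, set()).add(v)

    def D(dt):
        if dt == disease:
            return 1.0
        return max(delta * D(c) for c in children.get(dt, ()) if c in closure)

    contrib = {dt: D(dt) for dt in closure}
    return contrib, sum(contrib.values())


def mfs_oracle(disease_sets, ss, dpos):
    """Double-loop functional-similarity evaluation."""
    names = list(disease_sets)
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            di, dj = disease_sets[names[i]], disease_sets[names[j]]
            if i == j:
                out[i, j] = 1.0
                continue
            if not di and not dj:
                out[i, j] = 0.0
                continue
            if not di or not dj:
                out[i, j] = 0.0
                continue
            s1 = sum(max(ss[dpos[a], dpos[b]] for b in dj) for a in di)
            s2 = sum(max(ss[dpos[b], dpos[a]] for a in di) for b in dj)
            out[i, j] = (s1 + s2) / (len(di) + len(dj))
    return out


# ---------------------------------------------------------------- GIP kernel


class TestGipKernel:
    def test_worked_example(self, small_association):
        gm = gip_kernel(small_association)
        # lambda = 3/3 = 1; identical rows -> 1; ||r1 - r3||^2 = 2 -> e^-2
        assert gm.values[0, 1] == pytest.approx(1.0)
        assert gm.values[0, 2] == pytest.approx(np.exp(-2), abs=1e-12)

    def test_unit_diagonal(self, small_association):
        assert np.all(np.diag(gip_kernel(small_association).values) == 1.0)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_bruteforce_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        A = (rng.random((6, 9)) < 0.4).astype(int)
        A[A.sum(axis=1) == 0, 0] = 1
        assoc = AssociationMatrix(
            EntityIndex(tuple(f"m{i}" for i in range(6)), "mirna"),
            EntityIndex(tuple(f"d{j}" for j in range(9)), "disease"),
            A,
        )
        expected = gip_oracle(A)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(gip_kernel(assoc).values, expected, atol=1e-12)

    def test_identical_rows_iff_similarity_one(self, rng):
        A = (rng.random((8, 5)) < 0.5).astype(int)
        A[A.sum(axis=1) == 0, 0] = 1
        assoc = AssociationMatrix(
            EntityIndex(tuple(f"m{i}" for i in range(8)), "mirna"),
            EntityIndex(tuple(f"d{j}" for j in range(5)), "disease"),
            A,
        )
        gm = gip_kernel(assoc).values
        for i in range(8):
            for j in range(8):
                if np.array_equal(A[i], A[j]):
                    assert gm[i, j] == pytest.approx(1.0)
                else:
                    assert gm[i, j] < 1.0

    def test_all_zero_matrix_rejected(self):
        assoc = AssociationMatrix(
            EntityIndex(("m1",), "mirna"),
            EntityIndex(("d1",), "disease"),
            np.zeros((1, 1), dtype=int),
        )
        with pytest.raises(ValidationError, match="bandwidth"):
            gip_kernel(assoc)


# ---------------------------------------------------------------- alignment


class TestSmithWaterman:
    def test_self_alignment_is_match_times_length(self):
        assert smith_waterman_score("ACGU", "ACGU", AlignmentScoring(match=2)) == 8

    def test_no_positive_alignment_scores_zero(self):
        assert smith_waterman_score("AAAA", "CCCC") == 0.0

    def test_empty_sequence_scores_zero(self):
        assert smith_waterman_score("", "ACGU") == 0.0

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_dp_oracle_on_random_pairs(self, trial):
        rng = np.random.default_rng(200 + trial)
        scoring = AlignmentScoring(match=2.0, mismatch=-1.0, gap=-2.0)
        a = "".join(rng.choice(list("ACGU"), size=rng.integers(1, 13)))
        b = "".join(rng.choice(list("ACGU"), size=rng.integers(1, 13)))
        assert smith_waterman_score(a, b, scoring) == pytest.approx(
            sw_oracle(a, b, 2.0, -1.0, -2.0)
        )


class TestSequenceSimilarity:
    def test_worked_example(self):
        sp = np.array([[4.0, 2.0], [2.0, 9.0]])
        sw = sequence_similarity(sp, EntityIndex(("m1", "m2"), "mirna"))
        assert sw.values[0, 1] == pytest.approx(2 / 6)

    def test_diagonal_exactly_one(self, rng):
        base = rng.random((4, 4)) * 3
        sp = base @ base.T + 4 * np.eye(4)
        sw = sequence_similarity(sp, EntityIndex(tuple("abcd"), "mirna"))
        assert np.all(np.diag(sw.values) == 1.0)

    def test_zero_score_maps_to_zero(self):
        sp = np.array([[4.0, 0.0], [0.0, 9.0]])
        sw = sequence_similarity(sp, EntityIndex(("m1", "m2"), "mirna"))
        assert sw.values[0, 1] == 0.0

    def test_nonpositive_self_score_names_mirna(self):
        sp = np.array([[4.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValidationError, match="m2"):
            sequence_similarity(sp, EntityIndex(("m1", "m2"), "mirna"))


class TestFuseWithGip:
    def test_branches(self, mirna_index):
        S = np.array([[1.0, 0.4, 0.0], [0.4, 1.0, 0.0], [0.0, 0.0, 1.0]])
        G = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.3], [0.2, 0.3, 1.0]])
        fused = fuse_with_gip(
            SimilarityMatrix(mirna_index, S), SimilarityMatrix(mirna_index, G)
        )
        assert fused.values[0, 1] == 0.4  # positive entries kept
        assert fused.values[0, 2] == 0.2  # zeros back-filled
        assert fused.values[1, 2] == 0.3

    def test_all_positive_left_unchanged(self, mirna_index, rng):
        S = rng.uniform(0.1, 1.0, (3, 3))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        sim = SimilarityMatrix(mirna_index, S)
        fused = fuse_with_gip(sim, SimilarityMatrix(mirna_index, np.eye(3)))
        np.testing.assert_array_equal(fused.values, S)

    def test_index_mismatch_rejected(self, mirna_index):
        other = EntityIndex(("x1", "x2", "x3"), "mirna")
        with pytest.raises(ValidationError):
            fuse_with_gip(
                SimilarityMatrix(mirna_index, np.eye(3)),
                SimilarityMatrix(other, np.eye(3)),
            )


# ---------------------------------------------------------------- semantics


class TestSemanticValues:
    def test_chain_hand_recursion(self, chain_dag):
        cache = semantic_values(chain_dag, "C")
        assert cache.contributions == {"C": 1.0, "B": 0.5, "R": 0.25}
        assert cache.semantic_value == pytest.approx(1.75)

    def test_root_semantic_value_is_one(self, chain_dag):
        assert semantic_values(chain_dag, "R").semantic_value == 1.0

    def test_diamond_takes_max_over_paths(self):
        dag = DiseaseDAG.from_edges([("R", "A"), ("R", "B"), ("A", "C"), ("B", "C")])
        cache = semantic_values(dag, "C")
        assert cache.contributions["R"] == pytest.approx(0.25)
        assert cache.semantic_value == pytest.approx(2.25)

    def test_invariant_to_edge_insertion_order(self, rng):
        edges = [("R", "A"), ("R", "B"), ("A", "C"), ("B", "C"), ("A", "D")]
        base = semantic_values(DiseaseDAG.from_edges(edges), "C")
        for _ in range(5):
            shuffled = [edges[i] for i in rng.permutation(len(edges))]
            cache = semantic_values(DiseaseDAG.from_edges(shuffled), "C")
            assert cache.contributions == base.contributions

    @pytest.mark.parametrize("trial", range(15))
    def test_matches_recursive_oracle_on_random_dags(self, trial):
        rng = np.random.default_rng(300 + trial)
        n = int(rng.integers(4, 10))
        ids = [f"d{i}" for i in range(n)]
        edges = [(ids[int(rng.integers(i))], ids[i]) for i in range(1, n)]
        dag = DiseaseDAG.from_edges(edges)
        target = ids[int(rng.integers(1, n))]
        contrib, ds_val = semantic_oracle(edges, 0.5, target)
        cache = semantic_values(dag, target)
        assert cache.contributions == pytest.approx(contrib)
        assert cache.semantic_value == pytest.approx(ds_val)


class TestDiseaseSemanticSimilarity:
    def test_self_similarity_is_one(self, chain_dag):
        for d in ("R", "B", "C"):
            assert disease_semantic_similarity(chain_dag, d, d) == pytest.approx(1.0)

    def test_siblings_worked_example(self, sibling_dag):
        assert disease_semantic_similarity(sibling_dag, "A", "B") == pytest.approx(1 / 3)

    def test_disjoint_roots_similarity_zero(self):
        dag = DiseaseDAG.from_edges([("R1", "A"), ("R2", "B")])
        assert disease_semantic_similarity(dag, "A", "B") == 0.0

    def test_symmetric(self, chain_dag):
        ab = disease_semantic_similarity(chain_dag, "B", "C")
        ba = disease_semantic_similarity(chain_dag, "C", "B")
        assert ab == pytest.approx(ba)


# ---------------------------------------------------------------- functional


class TestFunctionalSimilarity:
    def test_identical_singleton_sets(self, sibling_dag):
        sets = {"m1": {"A"}, "m2": {"A"}}
        mfs = mirna_functional_similarity(sets, sibling_dag)
        assert mfs.values[0, 1] == pytest.approx(1.0)

    def test_sibling_singletons(self, sibling_dag):
        sets = {"m1": {"A"}, "m2": {"B"}}
        mfs = mirna_functional_similarity(sets, sibling_dag)
        assert mfs.values[0, 1] == pytest.approx(1 / 3)

    def test_empty_sets_zero_off_diagonal_one_on_diagonal(self, sibling_dag):
        sets = {"m1": set(), "m2": set()}
        mfs = mirna_functional_similarity(sets, sibling_dag)
        assert mfs.values[0, 1] == 0.0
        assert mfs.values[0, 0] == 1.0

    @pytest.mark.parametrize("trial", range(15))
    def test_matches_double_loop_oracle(self, trial):
        from miloc.similarity import semantic_similarity_matrix

        rng = np.random.default_rng(400 + trial)
        n_dis = int(rng.integers(3, 7))
        ids = [f"d{i}" for i in range(n_dis)]
        edges = [(ids[int(rng.integers(i))], ids[i]) for i in range(1, n_dis)]
        dag = DiseaseDAG.from_edges(edges)
        n_mir = int(rng.integers(2, 6))
        sets = {
            f"m{i}": {d for d in ids if rng.random() < 0.4}
            for i in range(n_mir)
        }
        ss = semantic_similarity_matrix(dag, ids)
        dpos = {d: i for i, d in enumerate(ids)}
        expected = mfs_oracle(sets, ss, dpos)
        got = mirna_functional_similarity(sets, dag)
        np.testing.assert_allclose(got.values, expected, atol=1e-12)


# ---------------------------------------------------------------- networks


class TestBinarizeNetwork:
    def _sim(self, values, index):
        return SimilarityMatrix(index, values)

    def test_threshold_one_gives_empty_graph(self, mirna_index, rng):
        S = rng.uniform(0, 1, (3, 3))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        g = binarize_network(self._sim(S, mirna_index), 1.0)
        assert g.n_edges == 0

    def test_threshold_zero_on_positive_matrix_gives_complete_graph(self, mirna_index):
        S = np.full((3, 3), 0.4)
        np.fill_diagonal(S, 1.0)
        g = binarize_network(self._sim(S, mirna_index), 0.0)
        assert g.n_edges == 3

    def test_strict_inequality(self, mirna_index):
        S = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.5], [0.3, 0.5, 1.0]])
        g = binarize_network(self._sim(S, mirna_index), 0.5)
        assert g.n_edges == 1
        assert g.has_edge("m1", "m2")

    def test_auto_threshold_targets_sparse_graph(self, rng):
        n = 30
        S = rng.uniform(0.3, 0.7, (n, n))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        index = EntityIndex(tuple(f"m{i}" for i in range(n)), "mirna")
        g = binarize_network(SimilarityMatrix(index, S), "auto")
        density = g.n_edges / (n * (n - 1) / 2)
        assert 0.05 < density < 0.15


# ------------------------------------------------------- output invariants


@pytest.mark.parametrize("trial", range(10))
def test_similarity_outputs_satisfy_matrix_invariants(trial):
    """Symmetry, unit diagonal and [0,1] range hold for every measure."""
    rng = np.random.default_rng(500 + trial)
    n = 6
    A = (rng.random((n, 10)) < 0.35).astype(int)
    A[A.sum(axis=1) == 0, 0] = 1
    index = EntityIndex(tuple(f"m{i}" for i in range(n)), "mirna")
    assoc = AssociationMatrix(index, EntityIndex(tuple(f"d{j}" for j in range(10)), "disease"), A)
    gm = gip_kernel(assoc)
    gm.validate()

    ids = [f"d{j}" for j in range(10)]
    edges = [(ids[int(rng.integers(i))], ids[i]) for i in range(1, 10)]
    dag = DiseaseDAG.from_edges(edges)
    sets = {f"m{i}": {ids[j] for j in np.flatnonzero(A[i])} for i in range(n)}
    mfs = mirna_functional_similarity(sets, dag, index)
    mfs.validate()
    fuse_with_gip(mfs, gm).validate()
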