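import itertools

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from vlwd.encodings import ColumnInfo, EncodingMatrix
from vlwd.likelihood import (
    BinaryTreeML,
    TwoStateModel,
    bootstrap,
    log_likelihood,
    nj_start_tree,
    optimize_branch_lengths,
    read_newick,
    search_tree,
    to_newick,
    transition_matrix,
)


def make_matrix(taxa, bits):
    bits = np.asarray(bits, dtype=np.uint8)
    cols = [ColumnInfo("site", str(j), 0) for j in range(bits.shape[1])]
    return EncodingMatrix(list(taxa), cols, bits, "vlbe1")


def random_matrix(taxa, ncols, seed):
    rng = np.random.default_rng(seed)
    return make_matrix(taxa, rng.integers(0, 2, size=(len(taxa), ncols)))


def exhaustive_loglik(tree, matrix, model):
    """Independent oracle: sum over all internal-state assignments."""
    rows = {t: matrix.bits[i] for i, t in enumerate(matrix.taxa)}
    nodes = list(tree.postorder_node_iter())
    internals = [nd for nd in nodes if not nd.is_leaf()]
    total = 0.0
    for col in range(matrix.width):
        colsum = 0.0
        for assign in itertools.product((0, 1), repeat=len(internals)):
            states = {id(nd): s for nd, s in zip(internals, assign)}
            for nd in nodes:
                if nd.is_leaf():
                    states[id(nd)] = int(rows[nd.taxon.label][col])
            p = model.pi[states[id(tree.seed_node)]]
            for nd in nodes:
                if nd is tree.seed_node:
                    continue
                P = model.transition_matrix(nd.edge.length)
                p *= P[states[id(nd.parent_node)], states[id(nd)]]
            colsum += p
        total += np.log(colsum)
    return total


class TestTransitionMatrix:
    @pytest.mark.parametrize("B", [1.0, 10.0, 1000.0])
    def test_identity_at_zero_and_row_sums(self, B):
        m = TwoStateModel(B)
        assert np.allclose(transition_matrix(m, 0.0), np.eye(2))
        for t in (0.001, 0.1, 5.0):
            P = transition_matrix(m, t)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert (P >= 0).all()

    @pytest.mark.parametrize("B", [1.0, 1000.0])
    def test_stationarity_limit(self, B):
        m = TwoStateModel(B)
        P = transition_matrix(m, 1e9)
        assert np.allclose(P, np.vstack([m.pi, m.pi]))

    @pytest.mark.parametrize("B,t", [(1.0, 0.3), (7.0, 0.05), (1000.0, 0.002)])
    def test_closed_form_matches_matrix_exponential(self, B, t):
        m = TwoStateModel(B)
        lam = m.rate
        Q = np.array([[-lam * m.pi[1], lam * m.pi[1]], [lam * m.pi[0], -lam * m.pi[0]]])
        assert np.allclose(transition_matrix(m, t), expm(Q * t), atol=1e-12)

    def test_symmetric_when_unbiased(self):
        P = transition_matrix(TwoStateModel(1.0), 0.7)
        assert np.isclose(P[0, 1], P[1, 0])

    def test_normalization_unit_flip_rate(self):
        # expected flips per site per unit t at stationarity == 1
        m = TwoStateModel(1000.0)
        dt = 1e-7
        P = transition_matrix(m, dt)
        flux = m.pi[0] * P[0, 1] + m.pi[1] * P[1, 0]
        assert np.isclose(flux / dt, 1.0, rtol=1e-4)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(TwoStateModel(), -0.1)

    def test_bad_bias_rejected(self):
        with pytest.raises(ValueError):
            TwoStateModel(0.0)


class TestLogLikelihood:
    def test_two_taxon_closed_form(self):
        m = TwoStateModel(50.0)
        mat = make_matrix(["A", "B"], [[0, 1, 1], [1, 1, 0]])
        t1, t2 = 0.003, 0.001
        tree = read_newick(f"(A:{t1},B:{t2});")
        P1, P2 = m.transition_matrix(t1), m.transition_matrix(t2)
        expected = 0.0
        for a, b in [(0, 1), (1, 1), (1, 0)]:
            expected += np.log(sum(m.pi[s] * P1[s, a] * P2[s, b] for s in (0, 1)))
        assert np.isclose(log_likelihood(tree, mat, m), expected, rtol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration_4_taxa(self, seed):
        m = TwoStateModel(1000.0)
        mat = random_matrix(["A", "B", "C", "D"], 15, seed)
        tree = read_newick("((A:0.001,B:0.004):0.002,C:0.0015,D:0.006);")
        ll = log_likelihood(tree, mat, m)
        oracle = exhaustive_loglik(tree, mat, m)
        assert abs(ll - oracle) <= 1e-10 * abs(oracle)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_exhaustive_enumeration_5_taxa(self, seed):
        m = TwoStateModel(10.0)
        mat = random_matrix(list("ABCDE"), 12, seed)
        tree = read_newick("((A:0.02,B:0.04):0.03,(C:0.01,E:0.08):0.02,D:0.05);")
        ll = log_likelihood(tree, mat, m)
        oracle = exhaustive_loglik(tree, mat, m)
        assert abs(ll - oracle) <= 1e-10 * abs(oracle)

    def test_root_invariance(self):
        m = TwoStateModel(1000.0)
        mat = random_matrix(list("ABCDEF"), 40, 9)
        tree = read_newick("((A:0.002,B:0.004):0.001,(C:0.001,(E:0.002,F:0.001):0.0005):0.002,D:0.005);")
        ref = log_likelihood(tree, mat, m)
        for edge in list(tree.preorder_edge_iter()):
            if edge.head_node is tree.seed_node or edge.length is None:
                continue
            t2 = tree.clone(depth=1)
            e2 = next(
                e for e in t2.preorder_edge_iter()
                if e.length == edge.length and e.head_node.is_leaf() == edge.head_node.is_leaf()
            )
            t2.reroot_at_edge(e2, length1=e2.length / 2, length2=e2.length / 2)
            assert abs(log_likelihood(t2, mat, m) - ref) < 1e-8

    def test_degenerate_zero_branch_identical_rows(self):
        m = TwoStateModel(4.0)
        mat = make_matrix(["A", "B", "C"], [[1, 0]] * 3)
        tree = read_newick("(A:0,B:0,C:0);")
        expected = np.log(m.pi[1]) + np.log(m.pi[0])
        assert np.isclose(log_likelihood(tree, mat, m), expected)

    def test_taxa_mismatch_rejected(self):
        m = TwoStateModel()
        mat = make_matrix(["A", "B", "C"], [[1], [0], [1]])
        with pytest.raises(ValueError, match="leaf set"):
            log_likelihood(read_newick("(A:1,B:1,X:1);"), mat, m)

    def test_missing_branch_length_rejected(self):
        m = TwoStateModel()
        mat = make_matrix(["A", "B", "C"], [[1], [0], [1]])
        with pytest.raises(ValueError, match="branch length"):
            log_likelihood(read_newick("(A:1,B:1,C);"), mat, m)


class TestBranchOptimization:
    def test_monotone_improvement_and_tol_exit(self):
        m = TwoStateModel(100.0)
        mat = random_matrix(list("ABCD"), 60, 5)
        tree = read_newick("((A:0.01,B:0.01):0.01,C:0.01,D:0.01);")
        ll0 = log_likelihood(tree, mat, m)
        opt = optimize_branch_lengths(tree, mat, m, tol=1e-6)
        trace = opt.optimization_trace
        assert opt.log_likelihood >= ll0
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))
        assert trace[-1] - trace[-2] < 1e-6

    def test_recovers_simulated_lengths(self):
        # abundant columns simulated on a known 4-taxon tree
        m = TwoStateModel(1.0)
        true = {"A": 0.15, "B": 0.25, "C": 0.2, "D": 0.3, "AB": 0.35}
        rng = np.random.default_rng(0)
        ncols = 40000
        root = rng.random(ncols) < m.pi[1]

        def evolve(states, t):
            P = m.transition_matrix(t)
            flip = rng.random(ncols) < np.where(states, P[1, 0], P[0, 1])
            return np.where(flip, ~states, states)

        ab = evolve(root, true["AB"])
        rows = {
            "A": evolve(ab, true["A"]), "B": evolve(ab, true["B"]),
            "C": evolve(root, true["C"]), "D": evolve(root, true["D"]),
        }
        mat = make_matrix(list("ABCD"), np.array([rows[t] for t in "ABCD"], dtype=np.uint8))
        tree = read_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")
        opt = optimize_branch_lengths(tree, mat, m, tol=1e-8)
        for leaf in opt.leaf_node_iter():
            assert abs(leaf.edge.length - true[leaf.taxon.label]) / true[leaf.taxon.label] < 0.2

    def test_bad_tol_rejected(self):
        m = TwoStateModel()
        mat = random_matrix(list("ABC"), 5, 1)
        with pytest.raises(ValueError):
            optimize_branch_lengths("(A:1,B:1,C:1);", mat, m, tol=0)


class TestSearch:
    def test_three_taxa_unique_topology(self):
        mat = random_matrix(list("ABC"), 20, 2)
        tree = search_tree(mat, TwoStateModel(), seed=0)
        assert len(tree.seed_node.child_nodes()) == 3
        assert all(c.is_leaf() for c in tree.seed_node.child_nodes())

    def test_likelihood_not_below_nj_start(self):
        m = TwoStateModel(1000.0)
        mat = random_matrix(list("ABCDEFG"), 80, 3)
        tree = search_tree(mat, m, seed=0)
        nj = optimize_branch_lengths(nj_start_tree(mat), mat, m)
        assert tree.log_likelihood >= nj.log_likelihood - 1e-6

    def test_deterministic_given_seed(self):
        mat = random_matrix(list("ABCDEF"), 50, 4)
        t1 = search_tree(mat, TwoStateModel(), seed=7, n_starts=2)
        t2 = search_tree(mat, TwoStateModel(), seed=7, n_starts=2)
        assert to_newick(t1) == to_newick(t2)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            search_tree(random_matrix(["A"], 5, 0), TwoStateModel())

    def test_recovers_tree_from_simulation(self):
        # low-divergence recovery: 10 leaves, rearrangement-only genomes
        from vlwd.adjacencies import build_profile
        from vlwd.encodings import encode
        from vlwd.evaluation import rf_error
        from vlwd.simulator import SimScenario, simulate
        from vlwd.genomes import gene_content

        failures = 0
        for seed in range(10):
            sc = SimScenario.from_preset("no_dup", n_leaves=10, n_genes=300, rate=1, seed=seed)
            res = simulate(sc)
            profile = build_profile(res.leaf_genomes)
            content = {g.name: gene_content(g) for g in res.leaf_genomes}
            mat = encode(profile, content, "vlbe1", reduce_invariant_columns=True)
            inferred = search_tree(mat, TwoStateModel(1000.0), seed=seed)
            if rf_error(to_newick(res.tree), inferred).rf_error_rate > 0:
                failures += 1
        assert failures <= 1


class TestBootstrap:
    def test_identical_sister_rows_full_support(self):
        rng = np.random.default_rng(0)
        bits = rng.integers(0, 2, size=(5, 60)).astype(np.uint8)
        bits[1] = bits[0]  # A2 identical to A1: (A1,A2) split certain
        mat = make_matrix(["A1", "A2", "B", "C", "D"], bits)
        tree = bootstrap(mat, TwoStateModel(), replicates=10, seed=3)
        labels = {}
        for nd in tree.postorder_internal_node_iter():
            if nd is tree.seed_node:
                continue
            side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            labels[side] = nd.label
        pair = frozenset({"A1", "A2"})
        matching = [v for k, v in labels.items() if k == pair or k == frozenset(mat.taxa) - pair]
        assert matching and float(matching[0]) == 100.0

    def test_supports_bounded_and_reproducible(self):
        mat = random_matrix(list("ABCDE"), 40, 8)
        t1 = bootstrap(mat, TwoStateModel(), replicates=5, seed=1)
        t2 = bootstrap(mat, TwoStateModel(), replicates=5, seed=1)
        assert to_newick(t1) == to_newick(t2)
        for nd in t1.postorder_internal_node_iter():
            if nd.label is not None:
                assert 0.0 <= float(nd.label) <= 100.0

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap(random_matrix(list("ABCD"), 10, 0), TwoStateModel(), replicates=0)


class TestModelFrontEnd:
    def test_fit_summary_and_results(self, example_genomes):
        res = BinaryTreeML.from_genomes(example_genomes, scheme="vlbe3").fit(seed=1)
        text = res.summary()
        assert "bias ratio" in text and "1000" in text
        assert f"{res.log_likelihood:.4f}" in text
        assert set(res.branch_lengths()["clade"]) == {"G1", "G2", "G3"}

    def test_default_bias_ratio_is_1000(self, example_genomes):
        model = BinaryTreeML.from_genomes(example_genomes)
        assert model.model.bias_ratio == 1000.0
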