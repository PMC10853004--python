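"""Marginal ancestral reconstruction: models, pruning, posteriors, recoding."""

import numpy as np
import pytest
from scipy.linalg import expm

from epistascape.asr import (
    AMINO_ACIDS,
    AncestralSequenceEstimate,
    SubstitutionModel,
    binary_recode,
    diff_replacements,
    discrete_gamma_rates,
    estimate_ancestral_sequence,
    load_tree,
    marginal_states,
    presence_posteriors,
    site_likelihood,
    site_log_likelihoods,
)
from epistascape.simulate import simulate_alignment

from conftest import enumeration_likelihood_and_posteriors, random_binary_newick

SMALL_ALPHABET = tuple("ACDE")


def small_model(seed=0):
    rng = np.random.default_rng(seed)
    freqs = rng.dirichlet(np.ones(4) * 5)
    return SubstitutionModel.equal_rates(SMALL_ALPHABET, freqs)


class TestSubstitutionModel:
    def test_transition_matrix_is_stochastic(self):
        m = small_model()
        for t in (0.0, 0.1, 1.0, 10.0):
            P = m.transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(P >= 0)
        assert np.allclose(m.transition_matrix(0.0), np.eye(4), atol=1e-12)

    def test_matches_scipy_expm(self):
        m = small_model(3)
        for t in (0.05, 0.7, 2.5):
            assert np.allclose(m.transition_matrix(t), expm(m.rate_matrix * t), atol=1e-10)

    def test_long_branch_reaches_stationarity(self):
        m = small_model(1)
        P = m.transition_matrix(500.0)
        assert np.allclose(P, np.tile(m.freqs, (4, 1)), atol=1e-8)

    def test_normalised_to_one_substitution_per_unit(self):
        m = SubstitutionModel.equal_rates()
        rate = -(m.freqs * np.diag(m.rate_matrix)).sum()
        assert rate == pytest.approx(1.0)

    def test_detailed_balance_enforced(self):
        Q = np.array([[-1.0, 1.0], [0.2, -0.2]])  # violates balance for pi=(.5,.5)
        with pytest.raises(ValueError, match="reversible"):
            SubstitutionModel(("0", "1"), Q, np.array([0.5, 0.5]))

    def test_binary_model_stationary(self):
        m = SubstitutionModel.binary(0.7)
        P = m.transition_matrix(100.0)
        assert P[0, 1] == pytest.approx(0.7, abs=1e-9)

    def test_gamma_rates_mean_one(self):
        rates = discrete_gamma_rates(0.5, 4)
        assert sum(r * w for r, w in rates) == pytest.approx(1.0)


class TestSiteLikelihood:
    def test_zero_branches_uniform_leaf_state(self):
        m = small_model()
        tree = "((A:0,B:0):0,C:0);"
        lik = site_likelihood(tree, {"A": "C", "B": "C", "C": "C"}, m)
        assert lik == pytest.approx(m.freqs[1], rel=1e-10)

    def test_long_branches_factorise_to_frequencies(self):
        m = small_model(2)
        tree = "((A:300,B:300):300,C:300);"
        lik = site_likelihood(tree, {"A": "A", "B": "C", "C": "E"}, m)
        assert lik == pytest.approx(m.freqs[0] * m.freqs[1] * m.freqs[3], rel=1e-6)

    def test_gap_is_missing_data(self):
        m = small_model()
        tree = "(A:0.2,B:0.3);"
        lik_gap = site_likelihood(tree, {"A": "A", "B": "-"}, m)
        total = sum(
            site_likelihood(tree, {"A": "A", "B": s}, m) for s in SMALL_ALPHABET
        )
        assert lik_gap == pytest.approx(total, rel=1e-10)

    def test_invalid_symbol(self):
        with pytest.raises(ValueError, match="symbol"):
            site_likelihood("(A:0.1,B:0.1);", {"A": "A", "B": "Z"}, small_model())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_on_random_trees(self, seed):
        """Pruning equals brute-force summation over internal states on
        random trees of up to 5 leaves, for 2- and 4-state models."""
        rng = np.random.default_rng(seed)
        n_leaves = int(rng.integers(3, 6))
        leaves = [f"L{i}" for i in range(n_leaves)]
        tree = random_binary_newick(leaves, rng)
        model = small_model(seed) if seed % 2 else SubstitutionModel.binary(0.3)
        chars = model.alphabet
        seqs = {l: "".join(rng.choice(chars, size=3)) for l in leaves}
        ll = site_log_likelihoods(tree, seqs, model)
        for s in range(3):
            oracle, _ = enumeration_likelihood_and_posteriors(tree, seqs, model, s)
            assert np.exp(ll[s]) == pytest.approx(oracle, abs=1e-10, rel=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_reroot_invariance(self, seed):
        """The pulley principle: likelihood under a reversible model does
        not depend on where along a branch the root is placed."""
        rng = np.random.default_rng(seed + 50)
        leaves = [f"L{i}" for i in range(5)]
        tree_text = random_binary_newick(leaves, rng)
        model = small_model(seed)
        seqs = {l: "".join(rng.choice(SMALL_ALPHABET, size=4)) for l in leaves}
        ll0 = site_log_likelihoods(load_tree(tree_text), seqs, model).sum()
        t2 = load_tree(tree_text)
        edge = next(
            e for e in t2.preorder_edge_iter()
            if e.head_node.taxon and e.head_node.taxon.label == "L2"
        )
        half = (edge.length or 0.1) / 2
        t2.reroot_at_edge(edge, length1=half, length2=half)
        ll2 = site_log_likelihoods(t2, seqs, model).sum()
        assert ll2 == pytest.approx(ll0, abs=1e-9)


class TestMarginalStates:
    def test_posteriors_normalised(self):
        m = small_model()
        tree = "((A:0.2,B:0.4)N1:0.3,(C:0.1,D:0.2)N2:0.2)root;"
        seqs = {"A": "AC", "B": "AD", "C": "CC", "D": "CD"}
        for p in marginal_states(tree, seqs, m, "N1"):
            assert sum(p.probabilities) == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_pattern_gives_half(self):
        m = SubstitutionModel.binary(0.5)
        tree = "((A:0.3,B:0.3)N1:0.1,(C:0.3,D:0.3)N2:0.1)root;"
        seqs = {"A": "0", "B": "1", "C": "0", "D": "1"}
        (p,) = marginal_states(tree, seqs, m, "root")
        assert p.probabilities[0] == pytest.approx(0.5, abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed + 10)
        leaves = [f"L{i}" for i in range(4)]
        tree = random_binary_newick(leaves, rng, name_internal=True)
        model = small_model(seed)
        seqs = {l: "".join(rng.choice(SMALL_ALPHABET, size=2)) for l in leaves}
        for s in range(2):
            _, oracle = enumeration_likelihood_and_posteriors(tree, seqs, model, s)
            for node, expected in oracle.items():
                got = marginal_states(tree, seqs, model, node)[s]
                assert np.allclose(got.probabilities, expected, atol=1e-10)

    def test_leaf_target_rejected(self):
        with pytest.raises(ValueError, match="leaf"):
            marginal_states("(A:0.1,B:0.1);", {"A": "A", "B": "C"}, small_model(), "A")

    def test_unknown_node(self):
        with pytest.raises(KeyError):
            marginal_states("(A:0.1,B:0.1)r;", {"A": "A", "B": "C"}, small_model(), "nope")


class TestBinaryRecode:
    def test_direct_mapping(self):
        matrix, names = binary_recode({"s1": "MK-V"})
        assert matrix.tolist() == [[1, 1, 0, 1]]

    def test_all_gap_column(self):
        matrix, _ = binary_recode({"a": "M-", "b": "K-"})
        assert matrix[:, 1].sum() == 0

    def test_column_sums_count_residues(self):
        seqs = {"a": "MK-V", "b": "M--V", "c": "-KLV"}
        matrix, _ = binary_recode(seqs)
        expected = [sum(c != "-" for c in col) for col in zip(*seqs.values())]
        assert matrix.sum(axis=0).tolist() == expected


class TestPresencePosteriors:
    def test_all_present_dominates(self):
        tree = "((A:0.3,B:0.5)N1:0.2,(C:0.2,D:0.4)N2:0.3)root;"
        seqs = {n: "QQ" for n in "ABCD"}
        pp = presence_posteriors(tree, seqs)
        for node, probs in pp.items():
            assert np.all(probs > 0.5)

    def test_symmetric_pattern(self):
        m = SubstitutionModel.binary(0.5)
        tree = "((A:0.3,B:0.3)N1:0.1,(C:0.3,D:0.3)N2:0.1)root;"
        seqs = {"A": "Q", "B": "-", "C": "Q", "D": "-"}
        pp = presence_posteriors(tree, seqs, m)
        assert pp["root"][0] == pytest.approx(0.5, abs=1e-10)

    def test_matches_enumeration_on_four_leaves(self):
        rng = np.random.default_rng(99)
        tree = random_binary_newick(["A", "B", "C", "D"], rng, name_internal=True)
        m = SubstitutionModel.binary(0.6)
        seqs = {"A": "Q-", "B": "QQ", "C": "--", "D": "Q-"}
        binseqs = {k: "".join("0" if c == "-" else "1" for c in v) for k, v in seqs.items()}
        pp = presence_posteriors(tree, seqs, m)
        for s in range(2):
            _, oracle = enumeration_likelihood_and_posteriors(tree, binseqs, m, s)
            for node, expected in oracle.items():
                assert pp[node][s] == pytest.approx(expected[1], abs=1e-10)


class TestAncestralEstimates:
    def test_diff_identical_empty(self):
        est = AncestralSequenceEstimate("X", ("M", "K"), (0.9, 0.8), (1.0, 1.0))
        assert len(diff_replacements(est, est)) == 0

    def test_planted_differences_counted(self):
        a = AncestralSequenceEstimate("anc", tuple("MKLVYQWERT"), (0.9,) * 10, (1.0,) * 10)
        desc_states = list("MKLVYQWERT")
        for i in (0, 2, 4, 6, 8):
            desc_states[i] = "A"
        d = AncestralSequenceEstimate("desc", tuple(desc_states), (0.9,) * 10, (1.0,) * 10)
        result = diff_replacements(a, d)
        assert len(result) == 5
        assert [r[0] for r in result.replacements] == [1, 3, 5, 7, 9]

    def test_presence_flip_reported_as_indel(self):
        a = AncestralSequenceEstimate("anc", ("M", "K"), (0.9, 0.9), (1.0, 0.1))
        d = AncestralSequenceEstimate("desc", ("M", "K"), (0.9, 0.9), (1.0, 0.9))
        result = diff_replacements(a, d)
        assert result.indels == ((2, "insertion"),)

    def test_coordinate_mismatch(self):
        a = AncestralSequenceEstimate("a", ("M",), (0.9,), (1.0,))
        b = AncestralSequenceEstimate("b", ("M", "K"), (0.9, 0.9), (1.0, 1.0))
        with pytest.raises(ValueError):
            diff_replacements(a, b)

    def test_end_to_end_estimate_gates_on_presence(self):
        tree = "((A:0.1,B:0.1)N1:0.1,(C:0.1,D:0.1)N2:0.1)root;"
        seqs = {"A": "QK--", "B": "QK--", "C": "QR--", "D": "QR--"}
        est = estimate_ancestral_sequence(
            tree, seqs, SubstitutionModel.equal_rates(), "N1"
        )
        assert est.sequence[:2] == "QK"
        assert est.sequence[2:] == "--"


class TestSimulationRecovery:
    def test_accuracy_improves_with_shorter_branches(self):
        """Average MAP recovery of the true root state grows as branch
        lengths shrink."""
        model = SubstitutionModel.equal_rates()
        leaves = [f"L{i}" for i in range(6)]
        accuracies = []
        for scale in (2.0, 0.5, 0.1):
            correct = total = 0
            for rep in range(4):
                rng = np.random.default_rng(1000 + rep)
                tree = random_binary_newick(leaves, rng, name_internal=True)
                t = load_tree(tree)
                for e in t.preorder_edge_iter():
                    if e.length:
                        e.length *= scale
                leaf_seqs, truth = simulate_alignment(t, model, 60, seed=rep)
                from epistascape.asr import _node_name

                root_name = _node_name(t.seed_node)
                posts = marginal_states(t, leaf_seqs, model, root_name)
                true_seq = truth.ancestral_sequences[root_name]
                correct += sum(p.map_state == c for p, c in zip(posts, true_seq))
                total += len(true_seq)
            accuracies.append(correct / total)
        assert accuracies[0] < accuracies[1] < accuracies[2]


class TestExchangeabilityFile:
    def test_round_trip_paml_layout(self, tmp_path):
        """A plain-text lower-triangular matrix plus frequency line loads
        into a valid reversible model."""
        import numpy as np

        from epistascape.asr import load_exchangeability_file

        rng = np.random.default_rng(0)
        k = 4
        S = np.zeros((k, k))
        tri = rng.uniform(0.2, 2.0, size=k * (k - 1) // 2)
        freqs = rng.dirichlet(np.ones(k) * 8)
        path = tmp_path / "model.dat"
        lines, it = [], iter(tri)
        for i in range(1, k):
            lines.append(" ".join(f"{next(it):.6f}" for _ in range(i)))
        lines.append(" ".join(f"{f:.6f}" for f in freqs))
        path.write_text("\n".join(lines) + "\n")
        m = load_exchangeability_file(path, alphabet=tuple("ACDE"))
        assert np.allclose(m.freqs, freqs / freqs.sum(), atol=1e-5)
        flux = m.freqs[:, None] * m.rate_matrix
        assert np.allclose(flux, flux.T, atol=1e-9)
        assert -(m.freqs * np.diag(m.rate_matrix)).sum() == pytest.approx(1.0)
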