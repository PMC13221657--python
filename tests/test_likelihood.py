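"""Likelihood engine vs exhaustive enumeration, closed forms, and
reversibility properties."""

import math

import numpy as np
import pytest

from cycadphylo import phyloio, simulate, trees
from cycadphylo.errors import ConsistencyError, InputError
from cycadphylo.likelihood import (
    MIN_BRANCH_LENGTH,
    log_likelihood,
    optimize_branch_lengths,
    poisson_model,
    quartet_log_likelihoods,
    read_paml_matrix,
)
from cycadphylo.phyloio import AMINO_ACIDS, AminoAlignment
from cycadphylo.simulate import SimulationConfig

from conftest import random_binary_tree, random_sequences
from oracles import brute_force_log_likelihood


class TestLogLikelihood:
    def test_two_identical_tips_at_zero_distance(self, model):
        tree = phyloio.parse_newick("(A:0,B:0);")
        aln = AminoAlignment("x", {"A": "W", "B": "W"})
        assert log_likelihood(tree, aln, model) == pytest.approx(
            math.log(1 / 20), abs=1e-9
        )

    def test_matches_exhaustive_enumeration_on_small_trees(self, model):
        rng = np.random.default_rng(5)
        for i in range(10):
            n_tips = int(rng.integers(3, 6))
            tree = random_binary_tree(rng, [f"t{j}" for j in range(n_tips)])
            aln = random_sequences(rng, [f"t{j}" for j in range(n_tips)], 8)
            impl = log_likelihood(tree, aln, model)
            oracle = brute_force_log_likelihood(tree, aln.rows, model)
            assert impl == pytest.approx(oracle, abs=1e-8)

    def test_gap_columns_contribute_zero(self, model):
        tree = phyloio.parse_newick("(A:0.1,B:0.1);")
        a1 = AminoAlignment("x", {"A": "WC", "B": "WD"})
        a2 = AminoAlignment("x", {"A": "WC--", "B": "WD--"})
        assert log_likelihood(tree, a1, model) == pytest.approx(
            log_likelihood(tree, a2, model), abs=1e-9
        )

    def test_invariant_under_rerooting(self, model):
        rng = np.random.default_rng(8)
        labels = [f"t{j}" for j in range(6)]
        tree = random_binary_tree(rng, labels)
        aln = random_sequences(rng, labels, 30)
        ref = log_likelihood(tree, aln, model)
        internal_ids = [
            i for i, n in enumerate(tree.preorder_node_iter())
            if not n.is_leaf() and n.parent_node is not None
        ]
        for target_index in internal_ids[:3]:
            rerooted = trees.clone(tree)
            node = list(rerooted.preorder_node_iter())[target_index]
            rerooted.reroot_at_node(node, update_bipartitions=False)
            assert log_likelihood(rerooted, aln, model) == pytest.approx(
                ref, abs=1e-6
            )

    def test_tip_without_sequence_raises(self, model):
        tree = phyloio.parse_newick("((A:1,B:1):1,C:1);")
        aln = AminoAlignment("x", {"A": "W", "B": "W"})
        with pytest.raises(ConsistencyError):
            log_likelihood(tree, aln, model)

    def test_no_underflow_on_large_trees(self, model):
        rng = np.random.default_rng(3)
        labels = [f"t{j:03d}" for j in range(500)]
        tree = random_binary_tree(rng, labels, min_bl=0.001, max_bl=0.05)
        aln = random_sequences(rng, labels, 1000)
        assert np.isfinite(log_likelihood(tree, aln, model))


class TestOptimizeBranchLengths:
    def test_two_tip_distance_matches_closed_form(self, model):
        rng = np.random.default_rng(0)
        n, d = 100_000, 0.05136
        pdiff = 19 / 20 * (1 - math.exp(-20 / 19 * d))
        s1 = rng.integers(0, 20, n)
        flip = rng.random(n) < pdiff
        s2 = np.where(flip, (s1 + rng.integers(1, 20, n)) % 20, s1)
        aln = AminoAlignment(
            "x",
            {
                "A": "".join(AMINO_ACIDS[i] for i in s1),
                "B": "".join(AMINO_ACIDS[i] for i in s2),
            },
        )
        tree = phyloio.parse_newick("(A:0.02,B:0.02);")
        fit = optimize_branch_lengths(tree, aln, model)
        total = sum(e.length for e in fit.tree.preorder_edge_iter() if e.length)
        p_hat = float((s1 != s2).mean())
        expected = -(19 / 20) * math.log(1 - (20 / 19) * p_hat)
        assert total == pytest.approx(expected, abs=1e-5)
        assert fit.converged

    def test_recovers_simulated_lengths_within_five_percent(self, model):
        cfg = SimulationConfig(seed=12, n_taxa=5, sites_per_locus=50_000)
        truth = phyloio.parse_newick(
            "((A:0.08,B:0.05):0.04,((C:0.06,D:0.09):0.03,E:0.07):0.05);"
        )
        aln = simulate.simulate_alignment(truth, cfg)
        start = trees.clone(truth)
        for e in start.preorder_edge_iter():
            if e.length:
                e.length = 0.05
        fit = optimize_branch_lengths(start, aln, model)
        true_d = trees.patristic_distances(truth)
        fit_d = trees.patristic_distances(fit.tree)
        for k, v in true_d.items():
            assert abs(fit_d[k] - v) / v < 0.05

    def test_identical_sequences_collapse_to_lower_bound(self, model):
        tree = phyloio.parse_newick("((A:0.1,B:0.1):0.1,C:0.1);")
        aln = AminoAlignment("x", {t: "ACDEFGHIKL" for t in "ABC"})
        fit = optimize_branch_lengths(tree, aln, model)
        for e in fit.tree.preorder_edge_iter():
            if e.head_node.parent_node is not None:
                assert e.length <= 2 * MIN_BRANCH_LENGTH + 1e-12

    def test_log_likelihood_not_decreased_by_optimization(self, model):
        rng = np.random.default_rng(9)
        labels = [f"t{j}" for j in range(6)]
        tree = random_binary_tree(rng, labels)
        aln = random_sequences(rng, labels, 60)
        before = log_likelihood(tree, aln, model)
        fit = optimize_branch_lengths(tree, aln, model)
        assert fit.log_likelihood >= before - 1e-9


class TestQuartets:
    def test_perfect_split_sites_pick_their_topology(self, model):
        rows = {"a": "AAAA" * 25, "b": "AAAA" * 25, "c": "CCCC" * 25, "d": "CCCC" * 25}
        lnls = quartet_log_likelihoods(AminoAlignment("q", rows), model)
        assert lnls[0] > lnls[1] + 2 and lnls[0] > lnls[2] + 2

    def test_constant_sites_are_symmetric(self, model):
        rows = {t: "W" * 50 for t in "abcd"}
        lnls = quartet_log_likelihoods(AminoAlignment("q", rows), model)
        assert max(lnls) - min(lnls) < 1e-6

    def test_row_order_relabels_topologies(self, model):
        rng = np.random.default_rng(4)
        rows = random_sequences(rng, ["a", "b", "c", "d"], 120).rows
        base = quartet_log_likelihoods(AminoAlignment("q", rows), model)
        swapped = AminoAlignment(
            "q", {k: rows[k] for k in ["a", "c", "b", "d"]}
        )
        perm = quartet_log_likelihoods(swapped, model)
        # (a,c|b,d) in swapped order is topology 0; in base order topology 1
        assert perm[0] == pytest.approx(base[1], abs=1e-4)
        assert perm[1] == pytest.approx(base[0], abs=1e-4)

    def test_fewer_than_four_rows_rejected(self, model):
        with pytest.raises(InputError):
            quartet_log_likelihoods(
                AminoAlignment("q", {"a": "W", "b": "W", "c": "W"}), model
            )


class TestPamlReader:
    def test_poisson_written_as_paml_matches_builtin(self, tmp_path, model):
        lines = []
        for i in range(1, 20):
            lines.append(" ".join("1.0" for _ in range(i)))
        lines.append("")
        lines.append(" ".join("0.05" for _ in range(20)))
        path = tmp_path / "poisson.dat"
        path.write_text("\n".join(lines) + "\n")
        m = read_paml_matrix(path)
        assert np.allclose(m.rate_matrix, model.rate_matrix, atol=1e-12)
        assert np.allclose(m.frequencies, model.frequencies)

    def test_rate_matrix_rows_sum_to_zero_and_unit_rate(self, tmp_path):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0.1, 5.0, size=190)
        freqs = rng.uniform(0.01, 0.1, size=20)
        freqs /= freqs.sum()
        text = []
        k = 0
        for i in range(1, 20):
            text.append(" ".join(f"{vals[k + j]:.6f}" for j in range(i)))
            k += i
        text.append(" ".join(f"{f:.6f}" for f in freqs))
        path = tmp_path / "m.dat"
        path.write_text("\n".join(text) + "\n")
        m = read_paml_matrix(path)
        assert np.allclose(m.rate_matrix.sum(axis=1), 0.0, atol=1e-10)
        assert -(m.frequencies * np.diag(m.rate_matrix)).sum() == pytest.approx(1.0)
        P = m.transition_matrix(0.7)
        assert np.allclose(P.sum(axis=1), 1.0)
        # detailed balance: pi_i P_ij = pi_j P_ji
        flux = m.frequencies[:, None] * P
        assert np.allclose(flux, flux.T, atol=1e-10)
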