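"""Penalized-likelihood dating: identifiability on clock trees, feasibility,
cross-validation rules, and calibration-boundedness classification."""

import numpy as np
import pytest

from cycadphylo import chronos, phyloio, trees
from cycadphylo.chronos import (
    Chronogram,
    check_calibration_boundedness,
    cross_validate,
    pl_date,
    prune_outgroup,
)
from cycadphylo.errors import (
    CalibrationError,
    IdentifiabilityError,
    InputError,
)
from cycadphylo.phyloio import CalibrationConstraint

from conftest import random_binary_tree

CLOCK_5 = "((A:0.03,B:0.03):0.07,((C:0.02,D:0.02):0.04,E:0.06):0.04);"
TRUE_AGES_5 = {
    frozenset({"A", "B"}): 30.0,
    frozenset({"C", "D"}): 20.0,
    frozenset({"C", "D", "E"}): 60.0,
    frozenset({"A", "B", "C", "D", "E"}): 100.0,
}


class TestPLDate:
    @pytest.mark.parametrize("lam", [1e-3, 1.0, 1e3])
    def test_exact_clock_with_fixed_root_recovers_truth(self, lam):
        tree = phyloio.parse_newick(CLOCK_5)
        cals = [CalibrationConstraint("root", "A", "E", 100.0, 100.0)]
        chron = pl_date(tree, cals, lam, n_sites=10_000, seed=2)
        for tips, true_age in TRUE_AGES_5.items():
            assert chron.ages[tips] == pytest.approx(true_age, rel=1e-3)

    def test_rates_reported_in_substitutions_per_site_per_ma(self):
        tree = phyloio.parse_newick(CLOCK_5)
        cals = [CalibrationConstraint("root", "A", "E", 100.0, 100.0)]
        chron = pl_date(tree, cals, 1.0, n_sites=10_000, seed=2)
        for rate in chron.rates.values():
            assert rate == pytest.approx(1e-3, rel=1e-3)

    def test_calibrated_nodes_respect_bounds(self):
        rng = np.random.default_rng(3)
        labels = [f"t{i}" for i in range(10)]
        tree = random_binary_tree(rng, labels, min_bl=0.01, max_bl=0.1)
        c1, c2 = tree.seed_node.child_nodes()
        tip_a = next(l.taxon.label for l in c1.leaf_iter())
        tip_b = next(l.taxon.label for l in c2.leaf_iter())
        cals = [
            CalibrationConstraint("root", tip_a, tip_b, 291.2, 358.9),
        ]
        chron = pl_date(tree, cals, 1.0, n_sites=5_000, seed=4)
        root_age = max(chron.ages.values())
        assert 291.2 - 1e-6 <= root_age <= 358.9 + 1e-6
        for node in chron.tree.preorder_node_iter():
            for child in node.child_nodes():
                assert node.age > child.age

    def test_infeasible_calibrations_name_the_pair(self):
        tree = phyloio.parse_newick(CLOCK_5)
        cals = [
            CalibrationConstraint("root", "A", "E", 100.0, 120.0),
            CalibrationConstraint("deep", "C", "E", 150.0, 200.0),  # child > root max
        ]
        with pytest.raises(CalibrationError) as excinfo:
            pl_date(tree, cals, 1.0, n_sites=1_000)
        # either member of the conflicting pair may be reported
        assert "deep" in str(excinfo.value) or "root" in str(excinfo.value)
        assert "infeasible" in str(excinfo.value)

    def test_root_without_finite_max_is_unidentifiable(self):
        tree = phyloio.parse_newick(CLOCK_5)
        cals = [CalibrationConstraint("cd", "C", "D", 10.0, 20.0)]
        with pytest.raises(IdentifiabilityError):
            pl_date(tree, cals, 1.0, n_sites=1_000)

    def test_smoothing_penalty_monotone_in_lambda(self):
        """The fitted rate-roughness term never increases when lambda grows
        tenfold."""
        tree = phyloio.parse_newick(
            "((A:0.08,B:0.02):0.07,((C:0.01,D:0.05):0.04,E:0.09):0.03);"
        )
        cals = [CalibrationConstraint("root", "A", "E", 100.0, 100.0)]

        def roughness(chron):
            rates = chron.rates
            root = chron.tree.seed_node
            pen = 0.0
            rr = []
            for node in chron.tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                r = rates[trees.leafset_below(node)]
                if node.parent_node is root:
                    rr.append(r)
                else:
                    rp = rates[trees.leafset_below(node.parent_node)]
                    pen += (r - rp) ** 2
            rr = np.array(rr)
            return pen + float(((rr - rr.mean()) ** 2).mean())

        values = [
            roughness(pl_date(tree, cals, lam, n_sites=20_000, seed=5))
            for lam in (0.1, 1.0, 10.0, 100.0)
        ]
        for a, b in zip(values, values[1:]):
            assert b <= a * (1 + 1e-6) + 1e-18


class TestPruneOutgroup:
    def test_tip_and_internal_node_counts(self):
        rng = np.random.default_rng(7)
        labels = [f"t{i:03d}" for i in range(346)] + ["OUTGROUP"]
        tree = random_binary_tree(rng, labels)
        pruned = prune_outgroup(tree, "OUTGROUP")
        assert len(trees.leaf_labels(pruned)) == 346
        internals = [
            n for n in pruned.preorder_internal_node_iter()
        ]
        assert len(internals) == 345

    def test_other_pairwise_distances_preserved(self):
        rng = np.random.default_rng(8)
        labels = [f"t{i}" for i in range(8)]
        tree = random_binary_tree(rng, labels)
        before = trees.patristic_distances(tree)
        pruned = prune_outgroup(tree, "t3")
        after = trees.patristic_distances(pruned)
        for (a, b), v in after.items():
            assert before[(a, b)] == pytest.approx(v, abs=1e-12)

    def test_non_tip_label_rejected(self):
        tree = phyloio.parse_newick(CLOCK_5)
        with pytest.raises(InputError):
            prune_outgroup(tree, "not_a_tip")


class TestCrossValidation:
    def test_clock_tree_scores_tie_and_largest_lambda_wins(self):
        tree = phyloio.parse_newick(CLOCK_5)
        cals = [CalibrationConstraint("root", "A", "E", 100.0, 100.0)]
        result = cross_validate(
            tree, cals, [0.01, 1.0, 100.0], n_sites=10_000, seed=1
        )
        scores = list(result.scores.values())
        assert max(scores) - min(scores) < 1e-6
        assert result.best_lambda == 100.0

    def test_two_point_grid_returns_one_of_them(self):
        tree = phyloio.parse_newick(CLOCK_5)
        cals = [CalibrationConstraint("root", "A", "E", 100.0, 100.0)]
        result = cross_validate(tree, cals, [0.5, 5.0], n_sites=10_000, seed=1)
        assert result.best_lambda in (0.5, 5.0)

    def test_determinism(self):
        tree = phyloio.parse_newick(
            "((A:0.05,B:0.02):0.06,((C:0.01,D:0.04):0.05,E:0.08):0.03);"
        )
        cals = [CalibrationConstraint("root", "A", "E", 100.0, 100.0)]
        r1 = cross_validate(tree, cals, [0.1, 10.0], n_sites=5_000, seed=3)
        r2 = cross_validate(tree, cals, [0.1, 10.0], n_sites=5_000, seed=3)
        assert r1.scores == r2.scores and r1.best_lambda == r2.best_lambda

    def test_non_positive_lambda_rejected(self):
        tree = phyloio.parse_newick(CLOCK_5)
        cals = [CalibrationConstraint("root", "A", "E", 100.0, 100.0)]
        with pytest.raises(InputError):
            cross_validate(tree, cals, [0.0, 1.0], n_sites=1_000)


class TestBoundedness:
    def _chronogram(self, ages):
        tree = phyloio.parse_newick(CLOCK_5)
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                node.age = 0.0
            else:
                node.age = ages[trees.leafset_below(node)]
        return Chronogram(tree, dict(ages), {}, 1.0, 0.0)

    def test_at_max_interior_and_fixed(self):
        ages = {
            frozenset({"A", "B"}): 107.67,
            frozenset({"C", "D"}): 64.56,
            frozenset({"C", "D", "E"}): 150.0,
            frozenset({"A", "B", "C", "D", "E"}): 358.9,
        }
        chron = self._chronogram(ages)
        cals = [
            CalibrationConstraint("crown", "A", "E", 291.2, 358.9),
            CalibrationConstraint("cd", "C", "D", 64.56 - 50, 64.56 + 50),
            CalibrationConstraint("ab", "A", "B", 107.67, 107.67),
        ]
        recs = {r.label: r for r in check_calibration_boundedness(chron, cals)}
        assert recs["crown"].status == "at_max"
        assert recs["crown"].position == pytest.approx(1.0)
        assert recs["cd"].status == "interior"
        assert recs["cd"].position == pytest.approx(0.5, abs=0.02)
        assert recs["ab"].status == "fixed"

    def test_backbone_interior_classification(self):
        ages = dict(TRUE_AGES_5)
        chron = self._chronogram(ages)
        # age 60 at 47% of [50, 71.2] -> interior (the 28-66% regime)
        cals = [CalibrationConstraint("cde", "C", "E", 50.0, 71.2)]
        (rec,) = check_calibration_boundedness(chron, cals)
        assert rec.status == "interior"
        assert 0.28 <= rec.position <= 0.66
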