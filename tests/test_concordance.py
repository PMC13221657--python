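"""Concordance-factor classification against explicit fixtures and the
restricted-bipartition oracle; site-concordance counting arithmetic."""

import numpy as np
import pytest

from cycadphylo import concordance, phyloio, simulate, trees
from cycadphylo.concordance import (
    gene_concordance,
    internal_branches,
    merge_concordance,
    site_concordance,
    summarize,
    annotate_tree,
)
from cycadphylo.errors import InputError, TreeValidationError
from cycadphylo.phyloio import AminoAlignment
from cycadphylo.simulate import SimulationConfig

from conftest import random_binary_tree
from oracles import gene_concordance_oracle

SPECIES_6 = "(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);"


class TestGeneConcordance:
    def test_identical_gene_trees_give_full_concordance(self):
        sp = phyloio.parse_newick(SPECIES_6)
        gts = [phyloio.parse_newick(SPECIES_6) for _ in range(7)]
        for rec in gene_concordance(sp, gts):
            assert rec.gcf == pytest.approx(100.0)
            assert rec.n_decisive_trees == 7

    def test_six_taxon_classification_fixture(self):
        """3 concordant + 1 NNI-alternative + 1 polyphyletic gene tree on the
        branch above the (A,B) cherry -> 60/20/0/20."""
        sp = phyloio.parse_newick(SPECIES_6)
        concordant = SPECIES_6
        # displays {A,C,D | B,E,F} = near1+far1 vs near2+far2 for branch (A,B)
        alt1 = "(((C:1,D:1):1,A:1):1,(B:1,(E:1,F:1):1):1);"
        # displays none of the three resolutions of that branch
        poly = "(((A:1,C:1):1,(B:1,D:1):1):1,(E:1,F:1):1);"
        gts = [phyloio.parse_newick(s) for s in [concordant] * 3 + [alt1, poly]]
        records = gene_concordance(sp, gts)
        rec = next(
            r for r in records
            if frozenset({"A", "B"}) in r.bipartition
        )
        assert rec.n_decisive_trees == 5
        assert rec.gcf == pytest.approx(60.0)
        assert rec.gdf1 + rec.gdf2 == pytest.approx(20.0)
        assert rec.gdfp == pytest.approx(20.0)
        assert rec.gcf + rec.gdf1 + rec.gdf2 + rec.gdfp == pytest.approx(
            100.0, abs=1e-6
        )

    def test_gene_tree_missing_a_block_is_not_decisive(self):
        sp = phyloio.parse_newick(SPECIES_6)
        # E absent: the root-adjacent branch loses far block {E} entirely,
        # while the (A,B) branch still has a far-block-2 representative (F)
        gt = phyloio.parse_newick("(((A:1,B:1):1,(C:1,D:1):1):1,F:1);")
        records = gene_concordance(sp, [gt])
        by_clade = {
            frozenset(min(r.bipartition, key=len)): r for r in records
        }
        ab = by_clade[frozenset({"A", "B"})]
        assert ab.n_decisive_trees == 1 and ab.gcf == 100.0
        abcd = by_clade[frozenset({"E", "F"})]
        assert abcd.n_decisive_trees == 0 and abcd.gcf is None

    def test_alien_tip_rejected(self):
        sp = phyloio.parse_newick(SPECIES_6)
        gt = phyloio.parse_newick("((A:1,ZZ:1):1,(C:1,D:1):1);")
        with pytest.raises(InputError) as excinfo:
            gene_concordance(sp, [gt])
        assert "ZZ" in str(excinfo.value)

    def test_unresolved_species_tree_rejected(self):
        sp = phyloio.parse_newick("((A:1,B:1,C:1):1,(D:1,E:1):1);")
        gt = phyloio.parse_newick("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);")
        with pytest.raises(TreeValidationError):
            gene_concordance(sp, [gt])

    def test_matches_restricted_bipartition_oracle(self):
        """Random <= 8-tip species/gene trees, with random tip drops."""
        rng = np.random.default_rng(17)
        for i in range(30):
            n = int(rng.integers(6, 9))
            labels = [f"t{j}" for j in range(n)]
            sp = random_binary_tree(rng, labels)
            gts = []
            for _ in range(6):
                gt = random_binary_tree(rng, labels)
                if rng.random() < 0.5 and n > 5:
                    drop = list(
                        rng.choice(labels, size=int(rng.integers(1, n - 4)),
                                   replace=False)
                    )
                    gt = trees.prune_tips(gt, drop)
                gts.append(gt)
            records = gene_concordance(sp, gts)
            by_id = {b.branch_id: b for b in internal_branches(sp)}
            for rec in records:
                branch = by_id[rec.branch_id]
                counts = [0, 0, 0, 0]
                n_dec = 0
                for gt in gts:
                    code = gene_concordance_oracle(branch, gt)
                    if code is None:
                        continue
                    n_dec += 1
                    counts[code] += 1
                assert rec.n_decisive_trees == n_dec
                if n_dec:
                    assert rec.gcf == pytest.approx(100 * counts[0] / n_dec)
                    assert rec.gdf1 == pytest.approx(100 * counts[1] / n_dec)
                    assert rec.gdf2 == pytest.approx(100 * counts[2] / n_dec)
                    assert rec.gdfp == pytest.approx(100 * counts[3] / n_dec)


class TestSiteConcordance:
    def test_perfectly_concordant_sites(self):
        sp = phyloio.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rows = {"A": "AC" * 30, "B": "AC" * 30, "C": "WD" * 30, "D": "WD" * 30}
        (rec,) = site_concordance(sp, AminoAlignment("m", rows))
        assert rec.scf == pytest.approx(100.0)

    def test_hand_counted_quartet_example(self):
        """10 sites: 6 concordant, 2 + 1 discordant, 1 non-decisive."""
        sp = phyloio.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        site_cols = (
            ["AACC"] * 6  # A==B, C==D -> concordant
            + ["ACAC"] * 2  # A==C, B==D -> first alternative
            + ["ACCA"]  # A==D, B==C -> second alternative
            + ["ACDE"]  # four distinct residues -> not decisive
        )
        rows = {
            lab: "".join(col[i] for col in site_cols)
            for i, lab in enumerate("ABCD")
        }
        (rec,) = site_concordance(sp, AminoAlignment("m", rows))
        assert rec.scf == pytest.approx(100 * 6 / 9, abs=1e-9)
        assert rec.mean_decisive_sites == pytest.approx(9.0)

    def test_gapped_site_is_never_decisive(self):
        sp = phyloio.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rows = {"A": "A-", "B": "A-", "C": "C-", "D": "C-"}
        (rec,) = site_concordance(sp, AminoAlignment("m", rows))
        assert rec.mean_decisive_sites == pytest.approx(1.0)

    def test_branch_without_decisive_sites_flagged_undefined(self):
        sp = phyloio.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rows = {"A": "ACDE", "B": "CDEA", "C": "DEAC", "D": "EACD"}
        (rec,) = site_concordance(sp, AminoAlignment("m", rows))
        assert not rec.scf_defined and rec.scf is None

    def test_sampled_equals_exhaustive_when_covering_all_quartets(self):
        cfg = SimulationConfig(seed=40, n_taxa=8, n_loci=1, sites_per_locus=400)
        sp = simulate.simulate_species_tree(cfg)
        gt = simulate.simulate_gene_trees(sp, cfg)[0]
        aln = simulate.simulate_alignment(gt, cfg)
        exhaustive = site_concordance(sp, aln, n_quartets=10**9, seed=1)
        sampled = site_concordance(sp, aln, n_quartets=10**9, seed=99)
        for a, b in zip(exhaustive, sampled):
            if a.scf_defined:
                assert a.scf == pytest.approx(b.scf, abs=1e-12)

    def test_likelihood_mode_agrees_on_clean_signal(self, model):
        sp = phyloio.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rows = {"A": "AC" * 20, "B": "AC" * 20, "C": "WD" * 20, "D": "WD" * 20}
        (rec,) = site_concordance(
            sp, AminoAlignment("m", rows), mode="likelihood", model=model
        )
        assert rec.scf == pytest.approx(100.0)


class TestSummaryAndAnnotation:
    def _records(self, gcfs, scfs=None):
        recs = []
        for i, g in enumerate(gcfs):
            r = concordance.BranchConcordance(
                f"b{i:03d}",
                frozenset({frozenset({f"x{i}", f"y{i}"}),
                           frozenset({f"z{i}", f"w{i}"})}),
            )
            r.gcf, r.gdf1, r.gdf2, r.gdfp = g, 0.0, 0.0, 100.0 - g
            r.n_decisive_trees = 10
            if scfs is not None:
                r.scf = scfs[i]
                r.scf_defined = True
            recs.append(r)
        return recs

    def test_median_and_threshold_arithmetic(self):
        s = summarize(self._records([2, 4, 10, 80]))
        assert s.median_gcf == pytest.approx(7.0)
        assert s.frac_gcf_below == pytest.approx(0.75)

    def test_single_branch_median(self):
        s = summarize(self._records([50]))
        assert s.median_gcf == pytest.approx(50.0)

    def test_scf_threshold_is_strict(self):
        s = summarize(self._records([50, 50], scfs=[100 / 3, 100 / 3]))
        assert s.frac_scf_above == 0.0

    def test_annotation_label_format_and_round_trip(self, tmp_path):
        sp = phyloio.parse_newick(SPECIES_6)
        grecs = gene_concordance(sp, [phyloio.parse_newick(SPECIES_6)] * 3)
        rows = {t: "AC" * 20 for t in "ABCDEF"}
        srecs = site_concordance(sp, AminoAlignment("m", rows))
        records = merge_concordance(grecs, srecs)
        records[0].gcf = 66.7
        records[0].scf = 85.5
        records[0].scf_defined = True
        annotated = annotate_tree(sp, records)
        text = phyloio.tree_to_newick(annotated)
        assert "66.7/85.5" in text
        back = phyloio.read_newick(tmp_path_write(tmp_path, text))
        assert "66.7/85.5" in phyloio.tree_to_newick(back)

    def test_undefined_scf_labeled_na(self):
        sp = phyloio.parse_newick(SPECIES_6)
        grecs = gene_concordance(sp, [phyloio.parse_newick(SPECIES_6)])
        for r in grecs:
            r.scf = None
            r.scf_defined = False
        annotated = annotate_tree(sp, grecs)
        assert "/NA" in phyloio.tree_to_newick(annotated)

    def test_empty_records_return_tree_unchanged(self):
        sp = phyloio.parse_newick(SPECIES_6)
        annotated = annotate_tree(sp, [])
        assert trees.same_topology(annotated, sp)

    def test_unmatched_record_raises(self):
        sp = phyloio.parse_newick(SPECIES_6)
        bogus = concordance.BranchConcordance(
            "b999", frozenset({frozenset({"A", "C"}), frozenset({"B", "D", "E", "F"})})
        )
        bogus.gcf = 1.0
        with pytest.raises(InputError):
            annotate_tree(sp, [bogus])


def tmp_path_write(tmp_path, text):
    p = tmp_path / "annot.nwk"
    p.write_text(text)
    return p
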