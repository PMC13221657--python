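"""Gene and site concordance factors for every internal species-tree branch.

For an internal branch of a fully resolved species tree, four taxon blocks
surround the branch: the two child clades on the near side and the two
blocks on the far side. A gene tree is *decisive* for the branch iff it
carries at least one taxon from each block; among decisive trees the
induced arrangement is classified as concordant (gCF), one of the two
nearest-neighbor-interchange alternatives (gDF1/gDF2), or neither (gDFP,
gene-tree polyphyly). Percentages are over decisive trees, so
gCF + gDF1 + gDF2 + gDFP = 100 on every decisive branch.

Site concordance samples quartets (one taxon per block) and scores
alignment sites. In counting mode a site is decisive for a quartet iff its
four residues are gap-free and show exactly two distinct residues, each
twice; the pairing picks one of the three topologies, and the branch sCF is
the mean over quartets of the concordant fraction (x100). Under no
phylogenetic signal the expectation is 33.3%. Likelihood mode instead fits
the three quartet topologies and lets each site vote for the topology with
the highest per-site log-likelihood.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from . import trees
from .errors import InputError, TreeValidationError
from .likelihood import (
    GAP_STATE,
    SubstitutionModel,
    encode_alignment,
    poisson_model,
    quartet_log_likelihoods,
)
from .phyloio import AminoAlignment

Bipartition = frozenset  # frozenset of the two frozenset sides


@dataclass
class Branch:
    """An internal branch of the species tree with its four taxon blocks."""

    branch_id: str
    near1: frozenset[str]
    near2: frozenset[str]
    far1: frozenset[str]
    far2: frozenset[str]

    @property
    def bipartition(self) -> Bipartition:
        return frozenset({self.near1 | self.near2, self.far1 | self.far2})


@dataclass
class BranchConcordance:
    branch_id: str
    bipartition: Bipartition
    gcf: float | None = None
    gdf1: float | None = None
    gdf2: float | None = None
    gdfp: float | None = None
    n_decisive_trees: int | None = None
    scf: float | None = None
    scf_defined: bool = False
    mean_decisive_sites: float | None = None
    n_quartets_used: int | None = None


@dataclass
class ConcordanceSummary:
    median_gcf: float
    frac_gcf_below: float
    mean_gdf1: float
    mean_gdf2: float
    mean_gdfp: float
    mean_scf: float
    frac_scf_above: float
    n_branches: int


def internal_branches(species_tree: dendropy.Tree) -> list[Branch]:
    """Enumerate internal branches (unrooted sense) with their four blocks.

    Near blocks are the attachment node's two child clades (in child order);
    far block 1 is the sibling clade, far block 2 the remainder. For the
    branch joining the two root children the far blocks are the sibling's
    two child clades. Requires a fully resolved tree.
    """
    if not trees.is_binary(species_tree):
        raise TreeValidationError("species tree must be fully resolved (binary)")
    all_tips = frozenset(trees.leaf_labels(species_tree))
    branches: list[Branch] = []
    root = species_tree.seed_node
    root_children = root.child_nodes()
    counter = 0
    for node in species_tree.preorder_internal_node_iter():
        if node is root:
            continue
        c1, c2 = (trees.leafset_below(c) for c in node.child_nodes())
        if node.parent_node is root:
            # unrooted edge between the two root children; emit once
            sib = root_children[1] if node is root_children[0] else root_children[0]
            if node is not root_children[0] or sib.is_leaf():
                continue
            f1, f2 = (trees.leafset_below(c) for c in sib.child_nodes())
        else:
            sib = [c for c in node.parent_node.child_nodes() if c is not node][0]
            f1 = trees.leafset_below(sib)
            f2 = all_tips - trees.leafset_below(node.parent_node)
        counter += 1
        branches.append(Branch(f"b{counter:03d}", c1, c2, f1, f2))
    return branches


def _gene_bipartitions(gene_tree: dendropy.Tree) -> set[Bipartition]:
    return trees.bipartition_set(gene_tree)


def gene_concordance(
    species_tree: dendropy.Tree, gene_trees: Sequence[dendropy.Tree]
) -> list[BranchConcordance]:
    """gCF/gDF1/gDF2/gDFP per internal branch over decisive gene trees.

    Gene trees may miss taxa; a tree lacking a whole block is not decisive
    for that branch. A gene-tree tip absent from the species tree is an
    error (prune paralogs first).
    """
    species_tips = frozenset(trees.leaf_labels(species_tree))
    gene_info = []
    for gt in gene_trees:
        tips = frozenset(trees.leaf_labels(gt))
        alien = tips - species_tips
        if alien:
            raise InputError(
                f"gene tree tip(s) not in species tree: {sorted(alien)}"
            )
        gene_info.append((tips, _gene_bipartitions(gt)))

    records = []
    for branch in internal_branches(species_tree):
        counts = [0, 0, 0, 0]  # concordant, df1, df2, polyphyletic
        n_decisive = 0
        for tips, bips in gene_info:
            a1 = branch.near1 & tips
            a2 = branch.near2 & tips
            b1 = branch.far1 & tips
            b2 = branch.far2 & tips
            if not (a1 and a2 and b1 and b2):
                continue
            n_decisive += 1
            if frozenset({a1 | a2, b1 | b2}) in bips:
                counts[0] += 1
            elif frozenset({a1 | b1, a2 | b2}) in bips:
                counts[1] += 1
            elif frozenset({a1 | b2, a2 | b1}) in bips:
                counts[2] += 1
            else:
                counts[3] += 1
        rec = BranchConcordance(branch.branch_id, branch.bipartition)
        rec.n_decisive_trees = n_decisive
        if n_decisive > 0:
            rec.gcf, rec.gdf1, rec.gdf2, rec.gdfp = (
                100.0 * c / n_decisive for c in counts
            )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Site concordance


def _sample_quartets(
    branch: Branch, n_quartets: int, rng: np.random.Generator
) -> list[tuple[str, str, str, str]]:
    blocks = [sorted(branch.near1), sorted(branch.near2),
              sorted(branch.far1), sorted(branch.far2)]
    total = 1
    for b in blocks:
        total *= len(b)
    if total <= n_quartets:
        return [
            (w, x, y, z)
            for w in blocks[0]
            for x in blocks[1]
            for y in blocks[2]
            for z in blocks[3]
        ]
    chosen: set[tuple[str, str, str, str]] = set()
    while len(chosen) < n_quartets:
        q = tuple(b[rng.integers(len(b))] for b in blocks)
        chosen.add(q)  # sampling without replacement within the branch
    return sorted(chosen)


def _quartet_site_votes(rows: np.ndarray) -> tuple[int, int, int, int]:
    """Counting-mode votes for one quartet: (concordant, df1, df2, decisive)."""
    r0, r1, r2, r3 = rows
    nogap = (rows < GAP_STATE).all(axis=0)
    conc = nogap & (r0 == r1) & (r2 == r3) & (r0 != r2)
    df1 = nogap & (r0 == r2) & (r1 == r3) & (r0 != r1)
    df2 = nogap & (r0 == r3) & (r1 == r2) & (r0 != r1)
    c, d1, d2 = int(conc.sum()), int(df1.sum()), int(df2.sum())
    return c, d1, d2, c + d1 + d2


def site_concordance(
    species_tree: dendropy.Tree,
    supermatrix: AminoAlignment,
    n_quartets: int = 1000,
    seed: int = 0,
    mode: str = "counting",
    model: SubstitutionModel | None = None,
) -> list[BranchConcordance]:
    """sCF per internal branch from quartet sampling over the supermatrix.

    Quartets draw one taxon per block, exhaustively when the total number of
    quartets is at most ``n_quartets`` (then the result is deterministic).
    Quartets containing an unsequenced taxon, or with no decisive site, do
    not enter the average; a branch where no quartet had a decisive site is
    flagged undefined. ``mode`` is ``counting`` (default) or ``likelihood``.
    """
    if n_quartets < 1:
        raise InputError("n_quartets must be >= 1")
    if mode not in ("counting", "likelihood"):
        raise InputError("mode must be 'counting' or 'likelihood'")
    rng = np.random.default_rng(seed)
    mat, labels = encode_alignment(supermatrix)
    row_of = {lab: i for i, lab in enumerate(labels)}
    missing = set(trees.leaf_labels(species_tree)) - set(labels)
    if missing:
        raise InputError(f"supermatrix lacks rows for tips: {sorted(missing)}")
    if mode == "likelihood":
        model = model or poisson_model()

    records = []
    for branch in internal_branches(species_tree):
        quartets = _sample_quartets(branch, n_quartets, rng)
        fractions = []
        decisive_counts = []
        for q in quartets:
            rows = mat[[row_of[t] for t in q]]
            if mode == "counting":
                c, d1, d2, dec = _quartet_site_votes(rows)
            else:
                c, d1, d2, dec = _quartet_likelihood_votes(
                    supermatrix, q, model
                )
            if dec == 0:
                continue
            fractions.append(c / dec)
            decisive_counts.append(dec)
        rec = BranchConcordance(branch.branch_id, branch.bipartition)
        rec.n_quartets_used = len(fractions)
        if fractions:
            rec.scf = 100.0 * float(np.mean(fractions))
            rec.scf_defined = True
            rec.mean_decisive_sites = float(np.mean(decisive_counts))
        records.append(rec)
    return records


def _quartet_likelihood_votes(
    supermatrix: AminoAlignment,
    quartet: tuple[str, str, str, str],
    model: SubstitutionModel,
) -> tuple[int, int, int, int]:
    sub = AminoAlignment(
        "quartet", {t: supermatrix.rows[t] for t in quartet}
    )
    _, site_lnl = quartet_log_likelihoods(sub, model, return_site_lnl=True)
    best = site_lnl.max(axis=0)
    margin = 1e-8
    votes = (site_lnl >= best - margin).sum(axis=0)
    decisive = votes == 1  # unique best topology
    winner = site_lnl.argmax(axis=0)
    c = int((decisive & (winner == 0)).sum())
    d1 = int((decisive & (winner == 1)).sum())
    d2 = int((decisive & (winner == 2)).sum())
    return c, d1, d2, c + d1 + d2


def merge_concordance(
    gene_records: Sequence[BranchConcordance],
    site_records: Sequence[BranchConcordance],
) -> list[BranchConcordance]:
    """Combine gene- and site-level records by bipartition."""
    by_bip = {r.bipartition: r for r in gene_records}
    for sr in site_records:
        gr = by_bip.get(sr.bipartition)
        if gr is None:
            raise InputError(f"site record for unknown branch {sr.branch_id}")
        gr.scf = sr.scf
        gr.scf_defined = sr.scf_defined
        gr.mean_decisive_sites = sr.mean_decisive_sites
        gr.n_quartets_used = sr.n_quartets_used
    return list(gene_records)


# ---------------------------------------------------------------------------
# Summaries and annotation


def _median(values: Sequence[float]) -> float:
    vals = sorted(values)
    n = len(vals)
    mid = n // 2
    return vals[mid] if n % 2 else 0.5 * (vals[mid - 1] + vals[mid])


def summarize(
    records: Sequence[BranchConcordance],
    gcf_threshold: float = 10.0,
    scf_threshold: float = 100.0 / 3.0,
) -> ConcordanceSummary:
    """Headline statistics: median gCF, fraction of branches at or below the
    gCF threshold, gDF means, mean sCF over defined branches, and the
    fraction strictly above the random-expectation sCF threshold."""
    if not records:
        raise InputError("no concordance records to summarize")
    gcfs = [r.gcf for r in records if r.gcf is not None]
    scfs = [r.scf for r in records if r.scf_defined and r.scf is not None]
    return ConcordanceSummary(
        median_gcf=_median(gcfs) if gcfs else float("nan"),
        frac_gcf_below=(
            sum(g <= gcf_threshold for g in gcfs) / len(gcfs) if gcfs else float("nan")
        ),
        mean_gdf1=float(np.mean([r.gdf1 for r in records if r.gdf1 is not None]))
        if gcfs
        else float("nan"),
        mean_gdf2=float(np.mean([r.gdf2 for r in records if r.gdf2 is not None]))
        if gcfs
        else float("nan"),
        mean_gdfp=float(np.mean([r.gdfp for r in records if r.gdfp is not None]))
        if gcfs
        else float("nan"),
        mean_scf=float(np.mean(scfs)) if scfs else float("nan"),
        frac_scf_above=(
            sum(s > scf_threshold for s in scfs) / len(scfs) if scfs else float("nan")
        ),
        n_branches=len(records),
    )


def annotate_tree(
    species_tree: dendropy.Tree, records: Sequence[BranchConcordance]
) -> dendropy.Tree:
    """Copy of the species tree with internal labels "gCF/sCF" (one decimal
    each; undefined sCF written as NA). Branches without a record keep their
    label; unknown records raise."""
    out = trees.clone(species_tree)
    if not records:
        return out
    by_bip = {r.bipartition: r for r in records}
    matched = set()
    all_tips = frozenset(trees.leaf_labels(out))
    for node in out.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = trees.leafset_below(node)
        bip = frozenset({side, all_tips - side})
        rec = by_bip.get(bip)
        if rec is None:
            continue
        matched.add(bip)
        gcf_s = f"{rec.gcf:.1f}" if rec.gcf is not None else "NA"
        scf_s = f"{rec.scf:.1f}" if rec.scf_defined and rec.scf is not None else "NA"
        node.label = f"{gcf_s}/{scf_s}"
    unmatched = set(by_bip) - matched
    if unmatched:
        raise InputError(
            f"{len(unmatched)} concordance record(s) match no branch of the tree"
        )
    return out


def branch_key(bipartition: Bipartition) -> str:
    """Stable short identifier for a bipartition (hash of both sorted sides)."""
    sides = sorted("|".join(sorted(s)) for s in bipartition)
    return hashlib.md5("||".join(sides).encode()).hexdigest()[:12]


def records_to_tsv(records: Sequence[BranchConcordance], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(
            "branch_id\tbipartition_hash\tclade\tgCF\tgDF1\tgDF2\tgDFP\t"
            "n_decisive_trees\tsCF\tmean_decisive_sites\tn_quartets\n"
        )
        for r in records:
            smaller = min(r.bipartition, key=lambda s: (len(s), sorted(s)))

            def fmt(x):
                return f"{x:.4f}" if x is not None else "NA"

            fh.write(
                f"{r.branch_id}\t{branch_key(r.bipartition)}\t"
                f"{','.join(sorted(smaller))}\t{fmt(r.gcf)}\t{fmt(r.gdf1)}\t"
                f"{fmt(r.gdf2)}\t{fmt(r.gdfp)}\t{r.n_decisive_trees}\t"
                f"{fmt(r.scf) if r.scf_defined else 'NA'}\t"
                f"{fmt(r.mean_decisive_sites)}\t{r.n_quartets_used}\n"
            )
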