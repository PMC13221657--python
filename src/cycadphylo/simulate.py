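"""Synthetic phylogenomic datasets with controllable discordance.

The generator emulates the statistical structure of a deep-time, slowly
evolving plant radiation sampled with transcriptome data: an ultrametric
pure-birth species tree with short internal branches, coalescent gene trees
whose discordance is driven by incomplete lineage sorting, a minority of
loci carrying a second (paralogous) copy in one accession, random taxon
missingness around a high occupancy target, and amino-acid alignments with
low per-locus signal.

Every random draw flows from the single ``seed`` in :class:`SimulationConfig`;
no operation consults global random state, so a fixed seed reproduces every
output bit-for-bit.

Units
-----
Species-tree branch durations are in Ma. Coalescent waiting times within a
species-tree branch of duration ``t`` are exponential with rate
``k(k-1)/2 / theta`` per Ma (equivalently, the branch spans ``t / theta``
coalescent time units). Gene-tree branch lengths are emitted in
substitutions/site: each lineage accrues ``duration * per_branch_rate *
multiplier`` along each species-tree branch it traverses. Multipliers are 1
(strict clock) when ``sigma_rate`` is 0; otherwise they are i.i.d.
log-normal with unit mean, drawn independently for every (locus, species
branch) pair and inherited by all gene-tree segments within that branch —
gene-specific rate variation, the among-locus component that the gene-wise
bootstrap downstream is designed to propagate. The ancestral segment above
the species root uses multiplier 1.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from . import phyloio, trees
from .errors import InputError
from .likelihood import SubstitutionModel, poisson_model
from .orthology import OccupancyMatrix
from .phyloio import AminoAlignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative knobs for one synthetic dataset.

    Defaults reproduce the qualitative regime of a densely sampled cycad-like
    phylogenomic study at desk scale: high taxon occupancy (~95%), a minority
    of loci with a second gene copy, coalescent discordance from short
    internal branches, and slow amino-acid evolution (~0.15 substitutions/site
    root to tip over a ~300 Ma crown).
    """

    seed: int = 0
    n_taxa: int = 20
    crown_age: float = 300.0  # Ma
    birth_rate: float = 0.03  # speciations per lineage per Ma
    theta: float = 10.0  # coalescent population-size parameter, Ma
    n_loci: int = 200
    sites_per_locus: int = 300
    per_branch_rate: float = 5e-4  # substitutions/site/Ma
    sigma_rate: float = 0.0  # log-normal sd of per-branch rate multipliers
    dup_fraction: float = 0.10  # fraction of loci receiving an extra copy
    dup_extra_depth: float = 0.2  # substitutions/site of extra divergence
    occupancy_target: float = 0.949  # expected per-locus taxon retention

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise InputError("n_taxa must be >= 3")
        if min(self.crown_age, self.birth_rate, self.per_branch_rate) <= 0:
            raise InputError("crown_age, birth_rate, per_branch_rate must be > 0")
        if self.theta <= 0:
            raise InputError("theta must be > 0")
        if not (0.0 <= self.dup_fraction <= 1.0):
            raise InputError("dup_fraction must be in [0, 1]")
        if self.dup_extra_depth < 0 or self.sigma_rate < 0:
            raise InputError("dup_extra_depth and sigma_rate must be >= 0")
        if not (0.0 < self.occupancy_target <= 1.0):
            raise InputError("occupancy_target must be in (0, 1]")
        if self.n_loci < 1 or self.sites_per_locus < 1:
            raise InputError("n_loci and sites_per_locus must be >= 1")


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Independent, named random stream derived from the config seed."""
    import zlib

    key = zlib.crc32(stream.encode("utf8"))
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
    )


# ---------------------------------------------------------------------------
# Species trees


def simulate_species_tree(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dendropy.Tree:
    """Pure-birth (Yule) species tree conditioned on ``n_taxa`` tips, with
    node ages rescaled so the crown (root) age equals ``crown_age`` exactly.

    Tips are labeled ``A001..A<n>``; every node carries ``.age`` (Ma) and the
    returned tree is ultrametric.
    """
    rng = rng if rng is not None else _rng(config, "species_tree")
    n = config.n_taxa
    b = config.birth_rate

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.is_rooted = True
    root = tree.seed_node
    root.birth_time = 0.0

    # Forward simulation: start from the crown split (2 lineages at t=0),
    # split a uniformly chosen lineage after Exp(k*b) waiting times.
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        child.birth_time = 0.0
        root.add_child(child)
        active.append(child)
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (k * b))
        lineage = active.pop(rng.integers(k))
        lineage.split_time = t
        for _ in range(2):
            child = dendropy.Node()
            child.birth_time = t
            lineage.add_child(child)
            active.append(child)
    # Extend tips past the last split so the youngest split is internal.
    present = t + rng.exponential(1.0 / (n * b))

    scale = config.crown_age / present
    idx = 0
    for node in tree.preorder_node_iter():
        if node is root:
            node.age = config.crown_age
            node.edge.length = None
            continue
        start = node.birth_time
        end = node.split_time if node.child_nodes() else present
        node.edge.length = (end - start) * scale
        node.age = config.crown_age - end * scale
        if not node.child_nodes():
            idx += 1
            taxon = taxon_ns.require_taxon(label=f"A{idx:03d}")
            node.taxon = taxon
            node.age = 0.0
    return tree


def species_phylogram(
    species_tree: dendropy.Tree, config: SimulationConfig
) -> dendropy.Tree:
    """Expected substitutions/site tree: each species branch scaled by
    ``duration * per_branch_rate``.

    Because per-locus rate multipliers have unit mean, this is the expected
    phylogram of a many-locus concatenation and serves as the ground-truth
    fixed topology for branch-length and dating recovery tests.
    """
    out = trees.clone(species_tree)
    src = list(species_tree.preorder_node_iter())
    dst = list(out.preorder_node_iter())
    for s_node, d_node in zip(src, dst):
        if s_node.parent_node is None:
            continue
        d_node.edge.length = (s_node.edge.length or 0.0) * config.per_branch_rate
    return out


# ---------------------------------------------------------------------------
# Multispecies-coalescent gene trees


class _Lineage:
    __slots__ = ("node", "last_age", "pending_subs")

    def __init__(self, node: dendropy.Node, age: float):
        self.node = node
        self.last_age = age
        self.pending_subs = 0.0

    def accrue(self, to_age: float, rate: float) -> None:
        self.pending_subs += (to_age - self.last_age) * rate
        self.last_age = to_age


def _coalesce_interval(
    lineages: list[_Lineage],
    age_lo: float,
    age_hi: float,
    rate: float,
    theta: float,
    rng: np.random.Generator,
) -> None:
    """Censored coalescent within [age_lo, age_hi] (age_hi=inf above root)."""
    t = age_lo
    while len(lineages) > 1:
        k = len(lineages)
        wait = rng.exponential(theta / (k * (k - 1) / 2.0))
        if t + wait >= age_hi:
            break
        t += wait
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        lj = lineages.pop(j)
        li = lineages.pop(i)
        parent = dendropy.Node()
        parent.age = t
        for child_lin in (li, lj):
            child_lin.accrue(t, rate)
            child_lin.node.edge.length = child_lin.pending_subs
            parent.add_child(child_lin.node)
        lineages.append(_Lineage(parent, t))
    if np.isfinite(age_hi):
        for lin in lineages:
            lin.accrue(age_hi, rate)


def simulate_gene_trees(
    species_tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_loci: int | None = None,
) -> list[dendropy.Tree]:
    """Censored multispecies-coalescent gene trees, one sampled lineage per
    species tip, with branch lengths in substitutions/site.

    Within each species-tree branch of duration ``t`` Ma, the ``k`` pending
    lineages coalesce at rate ``k(k-1)/2 / theta`` per Ma; lineages still
    unresolved at the species root coalesce in the ancestral population
    (rate multiplier 1). Each gene tree carries ``.locus_id``.
    """
    tol = 1e-9 * config.crown_age
    if not trees.is_ultrametric(species_tree, tol=tol):
        raise InputError("species tree must be ultrametric")
    rng = rng if rng is not None else _rng(config, "gene_trees")
    n_loci = n_loci if n_loci is not None else config.n_loci
    trees.set_node_ages(species_tree, tol=tol)

    out: list[dendropy.Tree] = []
    post_order = list(species_tree.postorder_node_iter())
    s = config.sigma_rate
    for locus_index in range(n_loci):
        # Gene-specific rate variation: one i.i.d. log-normal multiplier
        # (unit mean) per species-tree branch per locus. This among-locus
        # component is exactly what gene-wise resampling propagates.
        if s > 0:
            mults = {
                id(n): float(np.exp(rng.normal(-0.5 * s * s, s)))
                for n in post_order
                if n.parent_node is not None
            }
        else:
            mults = {}
        taxon_ns = dendropy.TaxonNamespace()
        surviving: dict[int, list[_Lineage]] = {}
        for sp_node in post_order:
            rate = config.per_branch_rate * mults.get(id(sp_node), 1.0)
            if sp_node.is_leaf():
                tip = dendropy.Node()
                tip.taxon = taxon_ns.require_taxon(label=sp_node.taxon.label)
                tip.age = 0.0
                pool = [_Lineage(tip, 0.0)]
            else:
                pool = []
                for child in sp_node.child_nodes():
                    pool.extend(surviving.pop(id(child)))
            if sp_node.parent_node is None:
                _coalesce_interval(
                    pool, sp_node.age, np.inf, config.per_branch_rate,
                    config.theta, rng,
                )
                root_lineage = pool[0]
            else:
                _coalesce_interval(
                    pool, sp_node.age, sp_node.parent_node.age, rate,
                    config.theta, rng,
                )
                surviving[id(sp_node)] = pool
        gene_tree = dendropy.Tree(taxon_namespace=taxon_ns)
        gene_tree.is_rooted = True
        gene_tree.seed_node = root_lineage.node
        gene_tree.locus_id = f"L{locus_index + 1:04d}"
        out.append(gene_tree)
    return out


# ---------------------------------------------------------------------------
# Paralogs and missingness


def inject_paralogs(
    gene_trees: Sequence[dendropy.Tree],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[dendropy.Tree]:
    """Add a second gene copy to one accession in a ``dup_fraction`` share
    of loci (Bernoulli per locus).

    The chosen accession's tip is relabeled ``<id>__1``; a new tip
    ``<id>__2`` attaches to the original pendant branch at height
    ``min(dup_extra_depth, 0.5 * pendant_length)`` above the tip, with
    pendant length ``attachment_height + dup_extra_depth``. The injected
    copy's patristic distance to every other accession therefore exceeds the
    original's by exactly ``dup_extra_depth``.
    """
    rng = rng if rng is not None else _rng(config, "paralogs")
    out = []
    for tree in gene_trees:
        locus_id = getattr(tree, "locus_id", None)
        new_tree = trees.clone(tree)
        new_tree.locus_id = locus_id
        if rng.random() < config.dup_fraction:
            leaves = list(new_tree.leaf_node_iter())
            target = leaves[int(rng.integers(len(leaves)))]
            acc = target.taxon.label
            pendant = target.edge.length or 0.0
            attach_height = min(config.dup_extra_depth, 0.5 * pendant)

            parent = target.parent_node
            junction = dendropy.Node()
            parent.remove_child(target)
            parent.add_child(junction)
            junction.edge.length = pendant - attach_height
            junction.add_child(target)
            target.edge.length = attach_height
            copy_tip = dendropy.Node()
            copy_tip.taxon = new_tree.taxon_namespace.require_taxon(
                label=f"{acc}__2"
            )
            junction.add_child(copy_tip)
            copy_tip.edge.length = attach_height + config.dup_extra_depth
            target.taxon = new_tree.taxon_namespace.require_taxon(label=f"{acc}__1")
        out.append(new_tree)
    return out


def _accession_of(label: str) -> str:
    return label.split("__")[0]


def apply_missingness(
    gene_trees: Sequence[dendropy.Tree],
    accession_ids: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[dendropy.Tree], OccupancyMatrix]:
    """Drop each accession from each locus independently with probability
    ``1 - occupancy_target``; return surviving trees plus the copy-count
    occupancy matrix. Loci left with fewer than 4 tips redraw their drop
    pattern (logged).
    """
    rng = rng if rng is not None else _rng(config, "missingness")
    accession_ids = list(accession_ids)
    counts = np.zeros((len(gene_trees), len(accession_ids)), dtype=int)
    out = []
    for li, tree in enumerate(gene_trees):
        tip_accessions = {_accession_of(lab) for lab in trees.leaf_labels(tree)}
        while True:
            keep = {
                acc
                for acc in accession_ids
                if rng.random() < config.occupancy_target
            }
            surviving_tips = [
                lab
                for lab in trees.leaf_labels(tree)
                if _accession_of(lab) in keep
            ]
            if len(surviving_tips) >= 4:
                break
            logger.info(
                "locus %s: < 4 tips after missingness; redrawing",
                getattr(tree, "locus_id", li),
            )
        drop = [
            lab for lab in trees.leaf_labels(tree) if lab not in surviving_tips
        ]
        new_tree = trees.prune_tips(tree, drop) if drop else trees.clone(tree)
        new_tree.locus_id = getattr(tree, "locus_id", None)
        out.append(new_tree)
        for lab in surviving_tips:
            counts[li, accession_ids.index(_accession_of(lab))] += 1
    locus_ids = [
        getattr(t, "locus_id", None) or f"L{i + 1:04d}" for i, t in enumerate(gene_trees)
    ]
    return out, OccupancyMatrix(counts, locus_ids, accession_ids)


# ---------------------------------------------------------------------------
# Sequence evolution


def simulate_alignment(
    gene_tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    model: SubstitutionModel | None = None,
) -> AminoAlignment:
    """Evolve amino-acid sequences along *gene_tree* (lengths in subs/site).

    Site-independent, single-rate model; default is the 20-state
    equal-exchangeability (Poisson) model. Root states draw from the model's
    stationary frequencies; each branch applies its transition matrix
    ``exp(Q * b)`` by per-site categorical sampling.
    """
    if len(trees.leaf_labels(gene_tree)) < 2:
        raise InputError("gene tree must have >= 2 tips")
    for edge in gene_tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise InputError("negative branch length in gene tree")
    rng = rng if rng is not None else _rng(config, "alignment")
    model = model or poisson_model()
    n_sites = config.sites_per_locus

    states: dict[int, np.ndarray] = {}
    rows: dict[str, str] = {}
    for node in gene_tree.preorder_node_iter():
        if node.parent_node is None:
            s = rng.choice(20, size=n_sites, p=model.frequencies)
        else:
            parent = states[id(node.parent_node)]
            P = model.transition_matrix(node.edge.length or 0.0)
            cum = np.cumsum(P, axis=1)
            cum[:, -1] = 1.0  # guard against rounding
            u = rng.random(n_sites)
            s = (cum[parent] < u[:, None]).sum(axis=1)
        states[id(node)] = s
        if node.is_leaf():
            rows[node.taxon.label] = "".join(phyloio.AMINO_ACIDS[i] for i in s)
    # deterministic row order: sorted by label
    rows = {k: rows[k] for k in sorted(rows)}
    return AminoAlignment(getattr(gene_tree, "locus_id", None) or "locus", rows)


# ---------------------------------------------------------------------------
# Whole-dataset orchestration


@dataclass
class SyntheticDataset:
    """Everything downstream stages need, plus the ground truth."""

    config: SimulationConfig
    species_tree: dendropy.Tree  # ultrametric, Ma, .age on nodes
    phylogram: dendropy.Tree  # same topology, substitutions/site
    gene_trees: list[dendropy.Tree]  # post paralog-injection + missingness
    alignments: list[AminoAlignment]
    occupancy: OccupancyMatrix
    accession_ids: list[str]

    def true_ages(self) -> dict[frozenset[str], float]:
        """True internal-node ages keyed by the node's descendant tip set."""
        out = {}
        for node in self.species_tree.preorder_internal_node_iter():
            out[trees.leafset_below(node)] = node.age
        return out


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generative chain for one dataset.

    Order: species tree -> coalescent gene trees (with per-locus branch
    rates) -> paralog injection -> missingness -> per-locus alignments.
    """
    species = simulate_species_tree(config)
    gene_trees = simulate_gene_trees(species, config)
    gene_trees = inject_paralogs(gene_trees, config)
    accession_ids = sorted(trees.leaf_labels(species))
    gene_trees, occupancy = apply_missingness(gene_trees, accession_ids, config)
    aln_rng = _rng(config, "alignment")
    alignments = [
        simulate_alignment(gt, config, rng=aln_rng) for gt in gene_trees
    ]
    return SyntheticDataset(
        config=config,
        species_tree=species,
        phylogram=species_phylogram(species, config),
        gene_trees=gene_trees,
        alignments=alignments,
        occupancy=occupancy,
        accession_ids=accession_ids,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write per-locus FASTA + Newick, occupancy TSV, the true species tree
    (node ages as internal labels), and a config echo."""
    outdir = Path(outdir)
    loci_dir = outdir / "loci"
    loci_dir.mkdir(parents=True, exist_ok=True)
    for tree, aln in zip(dataset.gene_trees, dataset.alignments):
        phyloio.write_fasta(aln, loci_dir / f"{aln.locus_id}.fasta")
        phyloio.write_newick(tree, loci_dir / f"{aln.locus_id}.nwk")
    dataset.occupancy.to_tsv(outdir / "occupancy.tsv")
    truth = trees.clone(dataset.species_tree)
    for node, src in zip(
        truth.preorder_node_iter(), dataset.species_tree.preorder_node_iter()
    ):
        if not node.is_leaf():
            node.label = f"{src.age:.6g}"
    phyloio.write_newick(truth, outdir / "species_tree_true.nwk")
    phyloio.write_newick(dataset.phylogram, outdir / "species_phylogram.nwk")
    with (outdir / "config.tsv").open("w") as fh:
        fh.write("key\tvalue\n")
        for f in dataclasses.fields(dataset.config):
            fh.write(f"{f.name}\t{getattr(dataset.config, f.name)}\n")
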