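import numpy as np
import pytest

from cycadphylo import phyloio, simulate, trees
from cycadphylo.likelihood import poisson_model
from cycadphylo.phyloio import AMINO_ACIDS, AminoAlignment


@pytest.fixture(scope="session")
def model():
    return poisson_model()


@pytest.fixture(scope="session")
def five_tip_tree():
    return phyloio.parse_newick(
        "((A:0.03,B:0.03):0.07,((C:0.02,D:0.02):0.04,E:0.06):0.04);"
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset reused by read-only tests."""
    cfg = simulate.SimulationConfig(
        seed=7, n_taxa=10, n_loci=30, sites_per_locus=120, theta=1.0,
        sigma_rate=0.2, dup_fraction=0.2, occupancy_target=0.9,
    )
    return simulate.simulate_dataset(cfg)


def random_sequences(rng, labels, n_sites):
    return AminoAlignment(
        "rand",
        {
            lab: "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, n_sites))
            for lab in labels
        },
    )


def random_binary_tree(rng, labels, min_bl=0.01, max_bl=0.5):
    """Random rooted binary tree by sequential joins, random branch lengths."""
    import dendropy

    ns = dendropy.TaxonNamespace()
    nodes = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = ns.require_taxon(label=lab)
        node.edge.length = float(rng.uniform(min_bl, max_bl))
        nodes.append(node)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = float(rng.uniform(min_bl, max_bl))
        nodes.append(parent)
    root = dendropy.Node()
    for n in nodes:
        root.add_child(n)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    tree.seed_node = root
    return tree
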