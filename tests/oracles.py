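"""Independent oracles used by unit and acceptance tests.

Each routine recomputes a quantity by a deliberately different method from
the implementation it checks: exhaustive state enumeration for tree
likelihoods, restricted-bipartition enumeration via dendropy's own
bipartition encoding for gene concordance, grid search plus generic
polishing for penalized-likelihood dating, and direct sort-and-interpolate
for percentiles.
"""

import itertools

import dendropy
import numpy as np

from cycadphylo.phyloio import AMINO_ACIDS


def brute_force_log_likelihood(tree, rows, model):
    """Sum over all internal-state assignments (trees with <= 5 tips)."""
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    idx = {id(n): i for i, n in enumerate(internals)}
    k = len(internals)
    P = {
        id(n): model.transition_matrix(n.edge.length or 0.0)
        for n in nodes
        if n.parent_node is not None
    }
    combos = np.array(np.meshgrid(*[range(20)] * k, indexing="ij")).reshape(k, -1)
    root_states = combos[idx[id(tree.seed_node)]]
    base = model.frequencies[root_states]
    for n in internals:
        if n.parent_node is not None:
            base = base * P[id(n)][
                combos[idx[id(n.parent_node)]], combos[idx[id(n)]]
            ]
    n_sites = len(next(iter(rows.values())))
    lnl = 0.0
    for s in range(n_sites):
        factor = base
        for leaf in tree.leaf_node_iter():
            ch = rows[leaf.taxon.label][s]
            if ch in "-X":
                continue
            obs = AMINO_ACIDS.index(ch)
            factor = factor * P[id(leaf)][combos[idx[id(leaf.parent_node)]], obs]
        lnl += np.log(factor.sum())
    return float(lnl)


def dendropy_bipartitions(tree):
    """Non-trivial bipartitions via dendropy's bitmask encoding."""
    tree = tree.clone(depth=1)
    tree.encode_bipartitions()
    all_taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    label_of = {}
    for taxon in tree.taxon_namespace:
        label_of[tree.taxon_namespace.taxon_bitmask(taxon)] = taxon.label
    bips = set()
    for bp in tree.bipartition_encoding:
        mask = bp.split_bitmask
        side = frozenset(
            lab for bit, lab in label_of.items() if bit & mask and lab in all_taxa
        )
        other = all_taxa - side
        if len(side) >= 2 and len(other) >= 2:
            bips.add(frozenset({side, other}))
    return bips


def gene_concordance_oracle(branch, gene_tree):
    """Classify one gene tree for one species-tree branch by enumerating the
    gene tree's bipartitions with dendropy (None = not decisive; 0 =
    concordant, 1/2 = the NNI alternatives, 3 = polyphyletic)."""
    tips = frozenset(l.taxon.label for l in gene_tree.leaf_node_iter())
    a1, a2 = branch.near1 & tips, branch.near2 & tips
    b1, b2 = branch.far1 & tips, branch.far2 & tips
    if not (a1 and a2 and b1 and b2):
        return None
    bips = dendropy_bipartitions(gene_tree)
    candidates = [
        frozenset({a1 | a2, b1 | b2}),
        frozenset({a1 | b1, a2 | b2}),
        frozenset({a1 | b2, a2 | b1}),
    ]
    for code, cand in enumerate(candidates):
        if cand in bips:
            return code
    return 3


def percentile_oracle(samples, pct):
    """Linear interpolation on the sorted sample, position 1 + p/100*(n-1)."""
    xs = sorted(samples)
    n = len(xs)
    pos = 1 + pct / 100.0 * (n - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return xs[lo - 1] * (1 - frac) + xs[hi - 1] * frac


def pl_objective(tree, n_sites, lam, ages, rates_by_node):
    """The penalized-likelihood objective recomputed from its definition."""
    nll = 0.0
    pen = 0.0
    root = tree.seed_node
    root_rates = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        x = (node.edge.length or 0.0) * n_sites
        d = ages[id(node.parent_node)] - ages.get(id(node), 0.0)
        r = rates_by_node[id(node)]
        mu = r * d
        nll -= x * np.log(mu) - mu if x > 0 else -mu
        if node.parent_node is root:
            root_rates.append(r)
        else:
            pen += (r - rates_by_node[id(node.parent_node)]) ** 2
    rr = np.array(root_rates)
    pen += float(((rr - rr.mean()) ** 2).mean())
    return nll + lam * pen


def grid_polish_date(tree, root_age, lam, n_sites, n_grid=8):
    """Date a small fixed-root tree by grid search over free internal ages
    with numerically optimized rates per grid point, then Nelder-Mead polish.

    Independent of the package's SLSQP path: objective re-implemented above,
    rates optimized by scipy on their own, ages searched exhaustively.
    """
    from scipy.optimize import minimize

    internals = [n for n in tree.preorder_internal_node_iter()]
    root = tree.seed_node
    free = [n for n in internals if n is not root]
    edge_nodes = [n for n in tree.preorder_node_iter() if n.parent_node is not None]

    def ages_from_vector(v):
        ages = {id(root): root_age}
        for node, val in zip(free, v):
            ages[id(node)] = val
        return ages

    def feasible(v):
        ages = ages_from_vector(v)
        for node in free:
            pa = ages[id(node.parent_node)]
            if not (1e-4 < ages[id(node)] < pa - 1e-4):
                return False
        return True

    def best_rates_and_value(v):
        ages = ages_from_vector(v)
        x = np.array([(n.edge.length or 0.0) * n_sites for n in edge_nodes])
        d = np.array(
            [ages[id(n.parent_node)] - ages.get(id(n), 0.0) for n in edge_nodes]
        )
        r0 = np.maximum(x / np.maximum(d, 1e-9), 1e-9)

        def obj(logr):
            rates = {id(n): rv for n, rv in zip(edge_nodes, np.exp(logr))}
            return pl_objective(tree, n_sites, lam, ages, rates)

        res = minimize(obj, np.log(r0), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000})
        return res.fun

    # grid over free ages within (0, root_age)
    axes = [np.linspace(root_age * 0.05, root_age * 0.95, n_grid) for _ in free]
    best_v, best_f = None, np.inf
    for combo in itertools.product(*axes):
        v = np.array(combo)
        if not feasible(v):
            continue
        f = best_rates_and_value(v)
        if f < best_f:
            best_f, best_v = f, v

    from scipy.optimize import minimize as m2

    def outer(v):
        if not feasible(v):
            return best_f + 1e6
        return best_rates_and_value(v)

    res = m2(outer, best_v, method="Nelder-Mead",
             options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 5000})
    ages = ages_from_vector(res.x)
    return res.fun, {id(n): ages[id(n)] for n in free}
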