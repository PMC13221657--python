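"""Minimal amino-acid likelihood engine.

Implements the pruning recursion for reversible 20-state models, coordinate-
wise branch-length optimization on a fixed topology (Brent per branch), and
quartet log-likelihoods. Single-rate models only: the engine's role here is
branch-length refresh for the gene-wise bootstrap and quartet fits for
likelihood-mode site concordance, neither of which needs among-site rate
heterogeneity.

Numerical notes
---------------
* Site patterns are compressed before any likelihood work; identical columns
  share one computation. In the low-signal regime this generator targets,
  most columns are constant, so compression is the main speed lever.
* Partial likelihoods are rescaled per pattern at every internal node; the
  scale is carried in log space, so 500-tip x 1,000-site problems stay finite.
* Branch lengths are bounded to [1e-8, 10] substitutions/site.
* On a rooted binary tree under a reversible model only the *sum* of the two
  root-child branch lengths is identifiable; the optimizer fits the sum and
  redistributes it across the pair in proportion to the input lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
import dendropy
import numpy as np

from .errors import ConsistencyError, InputError
from .phyloio import AMINO_ACIDS, AminoAlignment

logger = logging.getLogger(__name__)

MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 10.0
N_STATES = 20
GAP_STATE = N_STATES  # gaps and X are "missing": partial likelihood 1 everywhere


class SubstitutionModel:
    """Reversible amino-acid model: symmetric exchangeabilities + frequencies.

    The rate matrix Q is normalized to one expected substitution per site
    per unit branch length. Transition matrices come from the symmetric
    eigendecomposition of pi^(1/2) Q pi^(-1/2).
    """

    def __init__(self, exchangeabilities: np.ndarray, frequencies: np.ndarray,
                 name: str = "custom"):
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if S.shape != (N_STATES, N_STATES) or pi.shape != (N_STATES,):
            raise InputError("model must be 20x20 exchangeabilities + 20 frequencies")
        if not np.allclose(S, S.T):
            raise InputError("exchangeability matrix must be symmetric")
        if (pi <= 0).any():
            raise InputError("stationary frequencies must be positive")
        pi = pi / pi.sum()

        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        Q = Q / mu

        sq = np.sqrt(pi)
        B = Q * (sq[:, None] / sq[None, :])
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        self.name = name
        self.frequencies = pi
        self.rate_matrix = Q
        self._eigvals = w
        self._left = V / sq[:, None]  # pi^{-1/2} V
        self._right = V.T * sq[None, :]  # V^T pi^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows sum to 1; tiny negative entries clipped."""
        if t < 0:
            raise InputError("branch length must be >= 0")
        P = (self._left * np.exp(self._eigvals * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def poisson_model() -> SubstitutionModel:
    """20-state equal-exchangeability model with uniform frequencies."""
    S = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(S, 0.0)
    return SubstitutionModel(S, np.full(N_STATES, 1.0 / N_STATES), name="Poisson")


def read_paml_matrix(path: str | Path) -> SubstitutionModel:
    """Read a PAML-format .dat empirical model (lower-triangle
    exchangeabilities followed by 20 stationary frequencies)."""
    tokens: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0]
        for tok in line.split():
            try:
                tokens.append(float(tok))
            except ValueError:
                break  # trailing amino-acid name annotations
    need = 190 + 20
    if len(tokens) < need:
        raise InputError(
            f"{path}: expected at least {need} numbers "
            f"(190 exchangeabilities + 20 frequencies), found {len(tokens)}"
        )
    S = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            S[i, j] = S[j, i] = tokens[k]
            k += 1
    freqs = np.array(tokens[k : k + N_STATES])
    return SubstitutionModel(S, freqs, name=Path(path).stem)


# ---------------------------------------------------------------------------
# Alignment encoding and pattern compression

_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_CODE["X"] = GAP_STATE
_CODE["-"] = GAP_STATE


def encode_alignment(alignment: AminoAlignment) -> tuple[np.ndarray, list[str]]:
    """Rows as a (n_rows, n_sites) uint8 matrix; X and '-' map to the
    missing state."""
    labels = alignment.labels()
    mat = np.empty((len(labels), alignment.n_sites), dtype=np.uint8)
    table = np.zeros(128, dtype=np.uint8)
    for ch, code in _CODE.items():
        table[ord(ch)] = code
    for i, label in enumerate(labels):
        mat[i] = table[np.frombuffer(alignment.rows[label].encode("ascii"),
                                     dtype=np.uint8)]
    return mat, labels


def compress_patterns(
    matrix: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Unique columns and their multiplicities (weights may pre-weight sites)."""
    if weights is None:
        patterns, counts = np.unique(matrix, axis=1, return_counts=True)
        return patterns, counts.astype(float)
    patterns, inverse = np.unique(matrix, axis=1, return_inverse=True)
    w = np.zeros(patterns.shape[1])
    np.add.at(w, inverse.ravel(), weights)
    return patterns, w


# ---------------------------------------------------------------------------
# Pruning engine


class _Node:
    __slots__ = ("index", "children", "parent", "row", "length", "dnode")

    def __init__(self, index: int):
        self.index = index
        self.children: list["_Node"] = []
        self.parent: "_Node | None" = None
        self.row = -1  # pattern-matrix row for leaves
        self.length = 0.0
        self.dnode: dendropy.Node | None = None


class PruningEngine:
    """Felsenstein pruning on a fixed topology over compressed site patterns.

    ``down[v]`` is the conditional likelihood of the subtree below node v
    (per pattern, per state), ``M[v]`` the same viewed from v's parent
    (i.e. after crossing v's edge). Both carry per-pattern log-scales.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        patterns: np.ndarray,
        weights: np.ndarray,
        row_index: dict[str, int],
        model: SubstitutionModel,
    ):
        self.model = model
        self.patterns = patterns
        self.weights = np.asarray(weights, dtype=float)
        self.n_patterns = patterns.shape[1]

        self.nodes: list[_Node] = []
        self.postorder: list[_Node] = []
        by_dnode: dict[int, _Node] = {}
        for dnode in tree.postorder_node_iter():
            node = _Node(len(self.nodes))
            node.dnode = dnode
            self.nodes.append(node)
            by_dnode[id(dnode)] = node
            for child in dnode.child_nodes():
                cn = by_dnode[id(child)]
                cn.parent = node
                node.children.append(cn)
            if dnode.is_leaf():
                label = dnode.taxon.label
                if label not in row_index:
                    raise ConsistencyError(f"tip {label!r} has no sequence")
                node.row = row_index[label]
            node.length = max(dnode.edge.length or 0.0, 0.0)
            self.postorder.append(node)
        self.root = self.postorder[-1]
        self.root.length = 0.0

        npat = self.n_patterns
        self._down = [np.empty((npat, N_STATES)) for _ in self.nodes]
        self._down_scale = [np.zeros(npat) for _ in self.nodes]
        self._M = [np.empty((npat, N_STATES)) for _ in self.nodes]
        self._M_scale = [np.zeros(npat) for _ in self.nodes]
        self._leaf_partial: dict[int, np.ndarray] = {}
        for node in self.nodes:
            if node.row >= 0:
                states = patterns[node.row]
                part = np.zeros((npat, N_STATES))
                obs = states < N_STATES
                part[np.arange(npat)[obs], states[obs]] = 1.0
                part[~obs, :] = 1.0
                self._leaf_partial[node.index] = part
        self.full_down_pass()

    # -- core passes

    def _refresh_M(self, node: _Node) -> None:
        P = self.model.transition_matrix(node.length)
        np.matmul(self._down[node.index], P.T, out=self._M[node.index])
        self._M_scale[node.index][:] = self._down_scale[node.index]

    def _refresh_down(self, node: _Node) -> None:
        if not node.children:
            self._down[node.index][:] = self._leaf_partial[node.index]
            self._down_scale[node.index][:] = 0.0
            return
        d = self._down[node.index]
        s = self._down_scale[node.index]
        d[:] = self._M[node.children[0].index]
        s[:] = self._M_scale[node.children[0].index]
        for child in node.children[1:]:
            d *= self._M[child.index]
            s += self._M_scale[child.index]
        mx = d.max(axis=1)
        mx[mx <= 0.0] = 1.0
        d /= mx[:, None]
        s += np.log(mx)

    def full_down_pass(self) -> None:
        for node in self.postorder:
            self._refresh_down(node)
            if node is not self.root:
                self._refresh_M(node)

    def update_edge(self, node: _Node, new_length: float) -> None:
        """Set the length of the edge above *node* and refresh the arrays
        that depend on it (its M, and down/M of all ancestors)."""
        node.length = new_length
        self._refresh_M(node)
        anc = node.parent
        while anc is not None:
            self._refresh_down(anc)
            if anc is not self.root:
                self._refresh_M(anc)
            anc = anc.parent

    def log_likelihood(self) -> float:
        root = self.root
        site = self._down[root.index] @ self.model.frequencies
        good = site > 0.0
        if not good.all():
            # all-gap columns yield partial 1 everywhere -> site lik 1; a true
            # zero would mean an impossible pattern, which cannot happen with
            # P(t) > 0, so guard numerically only.
            site = np.where(good, site, np.finfo(float).tiny)
        return float(
            (self.weights * (np.log(site) + self._down_scale[root.index])).sum()
        )

    def site_log_likelihoods(self) -> np.ndarray:
        """Per-pattern log-likelihoods (order matches the pattern matrix)."""
        root = self.root
        site = self._down[root.index] @ self.model.frequencies
        site = np.where(site > 0, site, np.finfo(float).tiny)
        return np.log(site) + self._down_scale[root.index]

    # -- branch optimization

    def _path_from_root(self, node: _Node) -> list[_Node]:
        path = []
        cur: _Node | None = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent
        return path[::-1]

    def _edge_context(self, node: _Node) -> tuple[np.ndarray, np.ndarray]:
        """G[p, s] = likelihood of everything except node's subtree, with the
        state s at node's parent; returned with its log-scale."""
        path = self._path_from_root(node)
        G = np.tile(self.model.frequencies, (self.n_patterns, 1))
        scale = np.zeros(self.n_patterns)
        steps = 0
        for u, nxt in zip(path, path[1:]):
            for child in u.children:
                if child is nxt:
                    continue
                G = G * self._M[child.index]
                scale = scale + self._M_scale[child.index]
            steps += 1
            if steps % 8 == 0:  # occasional rescale; float64 headroom is ample
                mx = G.max(axis=1)
                mx[mx <= 0.0] = 1.0
                G /= mx[:, None]
                scale += np.log(mx)
            if nxt is not node:
                P = self.model.transition_matrix(nxt.length)
                G = G @ P
        mx = G.max(axis=1)
        mx[mx <= 0.0] = 1.0
        G = G / mx[:, None]
        scale = scale + np.log(mx)
        return G, scale

    def edge_log_likelihood(
        self, node: _Node, t: float, G: np.ndarray, G_scale: np.ndarray
    ) -> float:
        P = self.model.transition_matrix(t)
        H = self._down[node.index] @ P.T
        site = (G * H).sum(axis=1)
        site = np.where(site > 0, site, np.finfo(float).tiny)
        return float(
            (
                self.weights
                * (np.log(site) + G_scale + self._down_scale[node.index])
            ).sum()
        )

    def optimize_edge(self, node: _Node, xatol: float = 1e-8) -> float:
        """Optimize the edge above *node*; returns |change|.

        In the model's eigenbasis the per-pattern site likelihood along one
        edge is C[p] . exp(eigvals * t) with C fixed, so the univariate
        problem reduces to root-finding on an analytic derivative.
        """
        G, G_scale = self._edge_context(node)
        m = self.model
        C = (G @ m._left) * (self._down[node.index] @ m._right.T)
        w = self.weights
        lam = m._eigvals
        tiny = np.finfo(float).tiny

        def site(t):
            return np.maximum(C @ np.exp(lam * t), tiny)

        def fprime(t):
            return float((w * ((C @ (lam * np.exp(lam * t))) / site(t))).sum())

        lo, hi = MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH
        d_lo, d_hi = fprime(lo), fprime(hi)
        if d_lo <= 0.0:
            t_new = lo
        elif d_hi >= 0.0:
            t_new = hi
        else:
            from scipy.optimize import brentq

            t_new = float(brentq(fprime, lo, hi, xtol=xatol))
        old = node.length

        def value(t):
            return float((w * np.log(site(t))).sum())

        if value(t_new) < value(old):  # accept only improvements
            return 0.0
        change = abs(t_new - old)
        if change > 0:
            self.update_edge(node, t_new)
        return change

    def write_back(self) -> None:
        for node in self.nodes:
            if node is not self.root and node.dnode is not None:
                node.dnode.edge.length = node.length


@dataclass
class BranchLengthFit:
    tree: dendropy.Tree
    log_likelihood: float
    iterations: int
    converged: bool


def _prepare(
    tree: dendropy.Tree, alignment: AminoAlignment, model: SubstitutionModel
) -> PruningEngine:
    from . import trees as _t

    tips = _t.leaf_labels(tree)
    missing = [t for t in tips if t not in alignment.rows]
    if missing:
        raise ConsistencyError(f"tips without sequences: {missing}")
    sub = alignment.subset(tips)
    mat, labels = encode_alignment(sub)
    patterns, weights = compress_patterns(mat)
    row_index = {label: i for i, label in enumerate(labels)}
    return PruningEngine(tree, patterns, weights, row_index, model)


def log_likelihood(
    tree: dendropy.Tree, alignment: AminoAlignment, model: SubstitutionModel
) -> float:
    """Total log-likelihood of *alignment* on *tree* (fixed lengths).

    Gap/X cells are missing data (partial likelihood 1 in every state);
    all-gap columns contribute exactly 0.
    """
    return _prepare(tree, alignment, model).log_likelihood()


def optimize_branch_lengths(
    tree: dendropy.Tree,
    alignment: AminoAlignment,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_sweeps: int = 100,
    engine: PruningEngine | None = None,
) -> BranchLengthFit:
    """Coordinate-wise branch-length optimization on the fixed topology.

    Sweeps every branch with bounded Brent until the largest length change
    in a sweep is below *tol* or ``max_sweeps`` is hit. The log-likelihood
    is non-decreasing across accepted updates. The two root-child edges are
    fitted as their sum and redistributed in proportion to their input
    lengths (see module notes).
    """
    out_tree = tree if engine is not None else _clone_with_lengths(tree)
    eng = engine if engine is not None else _prepare(out_tree, alignment, model)

    root_children = eng.root.children
    pair = root_children if len(root_children) == 2 else []
    if pair:
        total0 = pair[0].length + pair[1].length
        w0 = pair[0].length / total0 if total0 > 0 else 0.5
        # Fold the pair's sum into pair[0] so Brent can reach any total.
        eng.update_edge(pair[0], max(total0 - MIN_BRANCH_LENGTH, MIN_BRANCH_LENGTH))
        eng.update_edge(pair[1], MIN_BRANCH_LENGTH)

    converged = False
    sweeps = 0
    order = [n for n in eng.postorder if n is not eng.root]
    last_change = {n.index: np.inf for n in order}
    for sweeps in range(1, max_sweeps + 1):
        max_change = 0.0
        for node in order:
            if pair and node is pair[1]:
                continue  # non-identifiable partner; handled via pair[0]
            if last_change[node.index] <= 0.1 * tol:
                continue  # converged edge; revisit only if neighbors move
            change = eng.optimize_edge(node)
            last_change[node.index] = change
            if change > tol:
                # neighbors' optima may shift; mark them active again
                for nb in ([node.parent] if node.parent else []) + node.children:
                    if nb is not None and nb is not eng.root:
                        last_change[nb.index] = np.inf
            max_change = max(max_change, change)
        if max_change < tol:
            converged = True
            break
    if pair:
        total = pair[0].length + pair[1].length
        a = min(max(total * w0, MIN_BRANCH_LENGTH), total)
        eng.update_edge(pair[0], a)
        eng.update_edge(pair[1], max(total - a, MIN_BRANCH_LENGTH))
    lnl = eng.log_likelihood()
    if not converged:
        logger.warning("branch-length optimization hit sweep cap (%d)", max_sweeps)
    eng.write_back()
    return BranchLengthFit(out_tree, lnl, sweeps, converged)


def _clone_with_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    from . import trees as _t

    out = _t.clone(tree)
    for edge in out.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = max(edge.length or 0.01, MIN_BRANCH_LENGTH)
    return out


# ---------------------------------------------------------------------------
# Quartets

_QUARTET_TOPOLOGIES = ((0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2))


def quartet_log_likelihoods(
    alignment: AminoAlignment,
    model: SubstitutionModel,
    return_site_lnl: bool = False,
):
    """Optimized log-likelihoods of the three unrooted quartet topologies.

    The alignment must have exactly 4 rows. Topologies are reported, in
    order, as (r0,r1|r2,r3), (r0,r2|r1,r3), (r0,r3|r1,r2) over the
    alignment's row order; each is fitted with all five free branch lengths
    optimized. With ``return_site_lnl`` the per-site log-likelihood matrix
    (3 x n_sites) is returned as well.
    """
    labels = alignment.labels()
    if len(labels) != 4:
        raise InputError("quartet likelihood needs exactly 4 rows")
    lnls = []
    site_rows = []
    for a, b, c, d in _QUARTET_TOPOLOGIES:
        newick = (
            f"(({_q(labels[a])}:0.05,{_q(labels[b])}:0.05):0.05,"
            f"({_q(labels[c])}:0.05,{_q(labels[d])}:0.05):0.05);"
        )
        qt = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        qt.is_rooted = True
        mat, mlabels = encode_alignment(alignment)
        patterns, inverse = np.unique(mat, axis=1, return_inverse=True)
        weights = np.zeros(patterns.shape[1])
        np.add.at(weights, inverse.ravel(), 1.0)
        row_index = {label: i for i, label in enumerate(mlabels)}
        eng = PruningEngine(qt, patterns, weights, row_index, model)
        fit = optimize_branch_lengths(qt, alignment, model, engine=eng)
        lnls.append(fit.log_likelihood)
        if return_site_lnl:
            site_rows.append(eng.site_log_likelihoods()[inverse.ravel()])
    if return_site_lnl:
        return np.array(lnls), np.vstack(site_rows)
    return np.array(lnls)


def _q(label: str) -> str:
    return label
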