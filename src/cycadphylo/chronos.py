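"""Penalized-likelihood divergence dating with hard min/max calibrations.

The estimator follows the classic semiparametric rate-smoothing approach:
node ages and per-branch substitution rates jointly minimize

    phi(a, r) = -sum_b [ x_b log(r_b d_b) - r_b d_b ]
                + lambda * [ sum_(b, parent(b)) (r_b - r_parent(b))^2
                             + Var(rates of the root's child branches) ]

where x_b is the branch's expected substitution count (branch length in
substitutions/site times the alignment width), d_b = age(parent) - age(child)
its duration in Ma, and lambda the smoothing weight. The first term is a
continuous-Poisson branch-length log-likelihood (non-integer counts are
allowed, which avoids rounding pathologies on short branches); the second
discourages abrupt rate changes between adjacent branches. Hard calibration
bounds and parent-older-than-child orderings are enforced as constraints.
The smoothing weight is chosen by leave-one-terminal-out cross-validation.

The root must carry a calibration with a finite maximum; otherwise the time
scale is unidentifiable and an error is raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize

from . import trees
from .errors import CalibrationError, IdentifiabilityError, InputError
from .phyloio import CalibrationConstraint

logger = logging.getLogger(__name__)

MIN_DURATION = 1e-6  # Ma; strict parent > child margin
_RATE_LB = 1e-12
_RATE_UB = 1e3


@dataclass
class Chronogram:
    """Dated tree: ultrametric topology plus per-branch rates."""

    tree: dendropy.Tree  # branch lengths in Ma; nodes carry .age
    ages: dict[frozenset, float]  # internal-node age keyed by descendant tips
    rates: dict[frozenset, float]  # branch rate keyed by head-node tip set
    smoothing: float
    objective: float

    def age_of(self, tips: frozenset) -> float:
        return self.ages[frozenset(tips)]


class _Problem:
    """Index arrays for one dating problem on a fixed rooted binary tree."""

    def __init__(
        self,
        tree: dendropy.Tree,
        calibrations: Sequence[CalibrationConstraint],
        n_sites: float,
    ):
        if not trees.is_binary(tree):
            raise InputError("tree must be rooted and fully resolved")
        self.tree = tree
        self.n_sites = n_sites
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.is_tip = np.array([n.is_leaf() for n in self.nodes])
        self.internal = [n for n in self.nodes if not n.is_leaf()]
        self.int_index = {id(n): i for i, n in enumerate(self.internal)}
        self.root = tree.seed_node

        # Edges: one per non-root node, indexed in postorder node order.
        self.edge_nodes = [n for n in self.nodes if n.parent_node is not None]
        self.x = np.array(
            [max(n.edge.length or 0.0, 0.0) * n_sites for n in self.edge_nodes]
        )

        # Calibration bounds per node.
        lo = {id(n): 0.0 for n in self.nodes}
        hi = {id(n): np.inf for n in self.nodes}
        self.calibrated: list[tuple[CalibrationConstraint, dendropy.Node]] = []
        for cal in calibrations:
            node = trees.mrca(tree, [cal.tip_a, cal.tip_b])
            lo[id(node)] = max(lo[id(node)], cal.min_ma)
            hi[id(node)] = min(hi[id(node)], cal.max_ma)
            self.calibrated.append((cal, node))

        # Propagate: a node can never be younger than any descendant's
        # minimum nor older than any ancestor's maximum.
        for n in self.nodes:  # postorder: children first
            for c in n.child_nodes():
                lo[id(n)] = max(lo[id(n)], lo[id(c)])
        for n in tree.preorder_node_iter():
            if n.parent_node is not None:
                hi[id(n)] = min(hi[id(n)], hi[id(n.parent_node)])
        for cal, node in self.calibrated:
            if lo[id(node)] > hi[id(node)] + 1e-12:
                raise CalibrationError(
                    f"calibration {cal.label!r} ({cal.tip_a}, {cal.tip_b}) is "
                    f"infeasible: effective bounds "
                    f"[{lo[id(node)]:g}, {hi[id(node)]:g}]"
                )
        if not np.isfinite(hi[id(self.root)]):
            raise IdentifiabilityError(
                "the root needs a calibration with a finite maximum age"
            )
        self.lo = np.array([max(lo[id(n)], MIN_DURATION) for n in self.internal])
        self.hi = np.array([hi[id(n)] for n in self.internal])
        root_hi = hi[id(self.root)]
        self.hi = np.where(np.isfinite(self.hi), self.hi, root_hi)
        bad = self.lo > self.hi + 1e-12
        if bad.any():
            raise CalibrationError("internally inconsistent calibration bounds")
        self.lo = np.minimum(self.lo, self.hi)

        # Edge incidence in age space: d_e = a[parent] - a[child].
        n_int = len(self.internal)
        n_edge = len(self.edge_nodes)
        self.e_parent = np.array(
            [self.int_index[id(n.parent_node)] for n in self.edge_nodes]
        )
        self.e_child = np.array(
            [self.int_index.get(id(n), -1) for n in self.edge_nodes]
        )
        # Smoothing pairs: edge e and the edge above its parent node.
        pairs = []
        for ei, n in enumerate(self.edge_nodes):
            p = n.parent_node
            if p is not None and p.parent_node is not None:
                pairs.append((ei, self.edge_nodes.index(p)))
        self.pairs = np.array(pairs, dtype=int).reshape(-1, 2)
        self.root_edges = np.array(
            [ei for ei, n in enumerate(self.edge_nodes) if n.parent_node is self.root]
        )
        self.n_int = n_int
        self.n_edge = n_edge

    # -- objective ---------------------------------------------------------

    def durations(self, ages: np.ndarray) -> np.ndarray:
        child_age = np.where(
            self.e_child >= 0, ages[np.maximum(self.e_child, 0)], 0.0
        )
        return ages[self.e_parent] - child_age

    def objective(self, z: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
        ages = z[: self.n_int]
        rates = z[self.n_int :]
        d = self.durations(ages)
        d_safe = np.maximum(d, 1e-12)
        r_safe = np.maximum(rates, _RATE_LB)
        mu = r_safe * d_safe
        nll = -(self.x * np.log(mu) - mu).sum()

        grad_r = -self.x / r_safe + d_safe
        dnll_dd = -self.x / d_safe + r_safe
        grad_a = np.zeros(self.n_int)
        np.add.at(grad_a, self.e_parent, dnll_dd)
        mask = self.e_child >= 0
        np.add.at(grad_a, self.e_child[mask], -dnll_dd[mask])

        pen = 0.0
        if self.pairs.size:
            diff = rates[self.pairs[:, 0]] - rates[self.pairs[:, 1]]
            pen += (diff**2).sum()
            np.add.at(grad_r, self.pairs[:, 0], lam * 2.0 * diff)
            np.add.at(grad_r, self.pairs[:, 1], -lam * 2.0 * diff)
        if self.root_edges.size:
            rr = rates[self.root_edges]
            dev = rr - rr.mean()
            pen += (dev**2).mean()
            np.add.at(
                grad_r, self.root_edges, lam * 2.0 * dev / self.root_edges.size
            )
        total = nll + lam * pen
        return total, np.concatenate([grad_a, grad_r])

    def roughness(self, z: np.ndarray) -> float:
        """The rate-penalty term alone (for the monotonicity diagnostic)."""
        rates = z[self.n_int :]
        pen = 0.0
        if self.pairs.size:
            pen += ((rates[self.pairs[:, 0]] - rates[self.pairs[:, 1]]) ** 2).sum()
        if self.root_edges.size:
            rr = rates[self.root_edges]
            pen += ((rr - rr.mean()) ** 2).mean()
        return float(pen)

    # -- constraints -------------------------------------------------------

    def ordering_constraints(self):
        """a[parent] - a[child] >= MIN_DURATION for internal children."""
        rows = [
            (self.e_parent[ei], self.e_child[ei])
            for ei in range(self.n_edge)
            if self.e_child[ei] >= 0
        ]
        A = np.zeros((len(rows), self.n_int + self.n_edge))
        for k, (p, c) in enumerate(rows):
            A[k, p] = 1.0
            A[k, c] = -1.0
        return {
            "type": "ineq",
            "fun": lambda z: A @ z - MIN_DURATION,
            "jac": lambda z: A,
        }

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        ages = np.zeros(self.n_int)
        order = [n for n in self.tree.preorder_node_iter() if not n.is_leaf()]
        for n in order:
            i = self.int_index[id(n)]
            lo, hi = self.lo[i], self.hi[i]
            if n.parent_node is not None:
                p_age = ages[self.int_index[id(n.parent_node)]]
                hi = min(hi, p_age - MIN_DURATION)
            hi = max(hi, lo)
            u = rng.uniform(0.25, 0.75)
            ages[i] = lo + u * (hi - lo)
        total_sub = self.x.sum()
        total_dur = self.durations(ages).sum()
        base = max(total_sub / max(total_dur, 1e-9), 1e-9)
        rates = base * np.exp(rng.normal(0.0, 0.2, size=self.n_edge))
        return np.concatenate([ages, rates])


def _finalize(
    problem: _Problem, z: np.ndarray, lam: float, objective: float
) -> Chronogram:
    ages = z[: problem.n_int].copy()
    # Project tiny solver violations back into the feasible box/ordering.
    ages = np.clip(ages, problem.lo, problem.hi)
    for n in problem.tree.preorder_node_iter():
        if n.is_leaf() or n.parent_node is None:
            continue
        i = problem.int_index[id(n)]
        p = problem.int_index[id(n.parent_node)]
        ages[i] = min(ages[i], ages[p] - MIN_DURATION)
    rates = np.maximum(z[problem.n_int :], _RATE_LB)

    out = trees.clone(problem.tree)
    src_nodes = list(problem.tree.postorder_node_iter())
    dst_nodes = list(out.postorder_node_iter())
    age_map: dict[frozenset, float] = {}
    rate_map: dict[frozenset, float] = {}
    for s, dnode in zip(src_nodes, dst_nodes):
        if s.is_leaf():
            dnode.age = 0.0
        else:
            dnode.age = float(ages[problem.int_index[id(s)]])
            age_map[trees.leafset_below(dnode)] = dnode.age
    for dnode in out.postorder_node_iter():
        if dnode.parent_node is not None:
            dnode.edge.length = dnode.parent_node.age - dnode.age
    # Internally rates act on expected counts; report substitutions/site/Ma.
    for ei, s in enumerate(problem.edge_nodes):
        key = trees.leafset_below(s)
        rate_map[key] = float(rates[ei] / problem.n_sites)
    chron = Chronogram(out, age_map, rate_map, lam, float(objective))
    _assert_feasible(chron, [c for c, _ in problem.calibrated])
    return chron


def _assert_feasible(
    chron: Chronogram, calibrations: Sequence[CalibrationConstraint], tol: float = 1e-6
) -> None:
    for node in chron.tree.preorder_node_iter():
        for c in node.child_nodes():
            if node.age <= c.age:
                raise CalibrationError("dated tree violates parent > child ages")
    for cal in calibrations:
        node = trees.mrca(chron.tree, [cal.tip_a, cal.tip_b])
        if not (cal.min_ma - tol <= node.age <= cal.max_ma + tol):
            raise CalibrationError(
                f"calibration {cal.label!r} violated: age {node.age:g} outside "
                f"[{cal.min_ma:g}, {cal.max_ma:g}]"
            )


def prune_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Remove the outgroup tip before dating; the resulting degree-2 root is
    suppressed with branch lengths summed."""
    tips = trees.leaf_labels(tree)
    if outgroup_label not in tips:
        raise InputError(f"outgroup {outgroup_label!r} is not a tip of the tree")
    return trees.prune_tips(tree, [outgroup_label])


def pl_date(
    tree: dendropy.Tree,
    calibrations: Sequence[CalibrationConstraint],
    lam: float,
    n_sites: float,
    n_starts: int = 5,
    seed: int = 0,
    max_iter: int = 500,
) -> Chronogram:
    """Date *tree* (branch lengths in substitutions/site) under smoothing
    weight ``lam``, returning the best of ``n_starts`` jittered local fits.

    Node ages honor every calibration's [min, max] and strict parent > child
    ordering; per-branch rates are in substitutions/site/Ma.
    """
    if lam < 0:
        raise InputError("smoothing lambda must be >= 0")
    if n_sites <= 0:
        raise InputError("n_sites must be positive")
    problem = _Problem(tree, calibrations, n_sites)
    rng = np.random.default_rng(seed)
    bounds = (
        [(problem.lo[i], problem.hi[i]) for i in range(problem.n_int)]
        + [(_RATE_LB, _RATE_UB)] * problem.n_edge
    )
    constraints = [problem.ordering_constraints()]

    best = None
    for _ in range(max(n_starts, 1)):
        z0 = problem.initial_point(rng)
        res = minimize(
            problem.objective,
            z0,
            args=(lam,),
            jac=True,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": max_iter, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise CalibrationError("penalized-likelihood optimization failed")
    return _finalize(problem, best.x, lam, best.fun)


# ---------------------------------------------------------------------------
# Cross-validation of the smoothing parameter


def default_lambda_grid() -> list[float]:
    """10^-3 .. 10^3 in decade steps."""
    return [10.0**k for k in range(-3, 4)]


@dataclass
class CrossValidationResult:
    best_lambda: float
    scores: dict[float, float]  # lambda -> summed chi-square score
    n_folds: int


def _remap_calibrations(
    full_tree: dendropy.Tree,
    calibrations: Sequence[CalibrationConstraint],
    dropped: str,
    pruned: dendropy.Tree,
) -> list[CalibrationConstraint]:
    out = []
    for cal in calibrations:
        clade = trees.leafset_below(trees.mrca(full_tree, [cal.tip_a, cal.tip_b]))
        remaining = sorted(clade - {dropped})
        if len(remaining) < 2:
            logger.info(
                "cross-validation fold %s: calibration %s reduces to a tip; skipped",
                dropped, cal.label,
            )
            continue
        node = trees.mrca(pruned, remaining)
        reps = sorted(trees.leafset_below(node))
        out.append(
            CalibrationConstraint(cal.label, reps[0], reps[-1], cal.min_ma, cal.max_ma)
        )
    return out


def cross_validate(
    tree: dendropy.Tree,
    calibrations: Sequence[CalibrationConstraint],
    lambda_grid: Sequence[float] | None = None,
    n_sites: float = 1.0,
    n_starts: int = 3,
    seed: int = 0,
) -> CrossValidationResult:
    """Leave-one-terminal-out cross-validation of the smoothing weight.

    For each tip, the terminal branch is dropped and the pruned tree dated;
    the dropped tip's substitution count along the path from its surviving
    ancestor is predicted as (sibling-lineage rate) x (that ancestor's
    reconstructed age) and scored as (observed - predicted)^2 / predicted.
    Tips attached directly to the root have no surviving ancestor and are
    skipped. Among lambdas whose summed score ties the minimum (within 1e-9
    relative), the largest wins.
    """
    grid = list(lambda_grid) if lambda_grid is not None else default_lambda_grid()
    if len(grid) < 2:
        raise InputError("lambda grid needs >= 2 values")
    if any(l <= 0 for l in grid):
        raise InputError("lambda grid values must be positive")

    folds = []
    for leaf in tree.leaf_node_iter():
        parent = leaf.parent_node
        if parent is None or parent.parent_node is None:
            continue  # no surviving ancestor to predict from
        grand = parent.parent_node
        sibling = [c for c in parent.child_nodes() if c is not leaf][0]
        observed = (
            (leaf.edge.length or 0.0) + (parent.edge.length or 0.0)
        ) * n_sites
        folds.append(
            {
                "tip": leaf.taxon.label,
                "observed": observed,
                "grand_tips": trees.leafset_below(grand),
                "sib_tips": trees.leafset_below(sibling),
            }
        )
    if not folds:
        raise InputError("tree too small for terminal-drop cross-validation")

    scores: dict[float, float] = {}
    for lam in grid:
        total = 0.0
        for fold in folds:
            pruned = trees.prune_tips(tree, [fold["tip"]])
            cals = _remap_calibrations(tree, calibrations, fold["tip"], pruned)
            chron = pl_date(
                pruned, cals, lam, n_sites, n_starts=n_starts, seed=seed
            )
            grand_remaining = sorted(fold["grand_tips"] - {fold["tip"]})
            g_node = trees.mrca(chron.tree, grand_remaining)
            rate = chron.rates[frozenset(fold["sib_tips"])]
            predicted = max(rate * n_sites * g_node.age, 1e-12)
            total += (fold["observed"] - predicted) ** 2 / predicted
        scores[lam] = total

    best_score = min(scores.values())
    tol = 1e-9 * (1.0 + abs(best_score))
    best_lambda = max(l for l, s in scores.items() if s <= best_score + tol)
    return CrossValidationResult(best_lambda, scores, len(folds))


# ---------------------------------------------------------------------------
# Calibration boundedness report


@dataclass
class BoundednessRecord:
    label: str
    age: float
    min_ma: float
    max_ma: float
    status: str  # at_min | at_max | interior | fixed
    position: float  # (age - min) / (max - min); nan for fixed


def check_calibration_boundedness(
    chronogram: Chronogram,
    calibrations: Sequence[CalibrationConstraint],
    tol: float = 0.5,
) -> list[BoundednessRecord]:
    """Classify each calibrated node as sitting at its minimum, its maximum
    (within *tol* Ma), or in the interior of its allowed interval."""
    out = []
    for cal in calibrations:
        node = trees.mrca(chronogram.tree, [cal.tip_a, cal.tip_b])
        age = node.age
        if cal.max_ma == cal.min_ma:
            out.append(
                BoundednessRecord(cal.label, age, cal.min_ma, cal.max_ma,
                                  "fixed", float("nan"))
            )
            continue
        position = (age - cal.min_ma) / (cal.max_ma - cal.min_ma)
        if age >= cal.max_ma - tol:
            status = "at_max"
        elif age <= cal.min_ma + tol:
            status = "at_min"
        else:
            status = "interior"
        out.append(
            BoundednessRecord(cal.label, age, cal.min_ma, cal.max_ma,
                              status, position)
        )
    return out


def boundedness_to_tsv(
    records: Sequence[BoundednessRecord], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("label\tage_ma\tmin_ma\tmax_ma\tstatus\tposition\n")
        for r in records:
            fh.write(
                f"{r.label}\t{r.age:.4f}\t{r.min_ma:g}\t{r.max_ma:g}\t"
                f"{r.status}\t{r.position:.4f}\n"
            )
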