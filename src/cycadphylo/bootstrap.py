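"""Gene-wise bootstrap confidence intervals for node ages.

Loci (not sites) are resampled with replacement; for each replicate the
branch lengths of the *fixed* topology are re-optimized on the replicate
supermatrix, the outgroup (if any) is pruned, the tree is re-dated under
the same calibrations and smoothing weight, and every internal-node age is
recorded keyed by the node's bipartition — stable across replicates because
the topology is never re-estimated. Percentile intervals (2.5th/97.5th by
default, linear interpolation) summarize the per-node age samples.

Because all replicates share one fixed topology, site patterns are pooled
across loci once; a replicate's supermatrix is represented by re-weighting
the pooled patterns with the drawn loci's counts, which makes the
branch-length refresh cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from . import trees
from .chronos import Chronogram, pl_date, prune_outgroup
from .errors import CycadPhyloError, InputError
from .likelihood import (
    PruningEngine,
    SubstitutionModel,
    encode_alignment,
    optimize_branch_lengths,
)
from .phyloio import AminoAlignment, CalibrationConstraint

logger = logging.getLogger(__name__)


def percentile_ci(
    samples: Sequence[float], lower_pct: float = 2.5, upper_pct: float = 97.5
) -> tuple[float, float]:
    """Linear-interpolation percentile interval on the sorted sample
    (position = 1 + p/100 * (n - 1))."""
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise InputError("cannot take percentiles of an empty sample")
    if not (0 <= lower_pct <= upper_pct <= 100):
        raise InputError("percentiles must satisfy 0 <= lower <= upper <= 100")
    lo, hi = np.percentile(arr, [lower_pct, upper_pct], method="linear")
    return float(lo), float(hi)


@dataclass
class AgeSampleTable:
    """Per-node bootstrap age samples plus percentile CIs."""

    samples: dict[frozenset, list[float]]  # node bipartition -> ages (Ma)
    n_replicates: int
    lower_pct: float = 2.5
    upper_pct: float = 97.5

    def nodes(self) -> list[frozenset]:
        """Deterministic node order: by clade size, then sorted tip labels."""
        return sorted(self.samples, key=lambda s: (len(s), tuple(sorted(s))))

    def ci(self, node: frozenset) -> tuple[float, float]:
        return percentile_ci(self.samples[node], self.lower_pct, self.upper_pct)

    def cis(self) -> dict[frozenset, tuple[float, float]]:
        return {node: self.ci(node) for node in self.nodes()}

    def mean_ci_width(self) -> float:
        widths = [hi - lo for lo, hi in self.cis().values()]
        return float(np.mean(widths))

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"# n_replicates\t{self.n_replicates}\n")
            fh.write(f"# percentiles\t{self.lower_pct:.17g}\t{self.upper_pct:.17g}\n")
            fh.write("tips\tages\n")
            for node in self.nodes():
                ages = ",".join(f"{a:.17g}" for a in self.samples[node])
                fh.write(f"{','.join(sorted(node))}\t{ages}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AgeSampleTable":
        n_rep = 0
        lower, upper = 2.5, 97.5
        samples: dict[frozenset, list[float]] = {}
        for line in Path(path).read_text().splitlines():
            if line.startswith("# n_replicates"):
                n_rep = int(line.split("\t")[1])
            elif line.startswith("# percentiles"):
                _, lo, hi = line.split("\t")
                lower, upper = float(lo), float(hi)
            elif line and not line.startswith(("#", "tips\t")):
                tips, ages = line.split("\t")
                samples[frozenset(tips.split(","))] = [
                    float(a) for a in ages.split(",")
                ]
        return cls(samples, n_rep, lower, upper)


class _ReplicateLikelihood:
    """Pooled site patterns over all loci; a replicate is a weight vector."""

    def __init__(
        self,
        loci: Sequence[AminoAlignment],
        labels: Sequence[str],
        model: SubstitutionModel,
    ):
        self.model = model
        self.labels = list(labels)
        mats = []
        self.locus_sites = []
        for aln in loci:
            gap_row = "-" * aln.n_sites
            padded = AminoAlignment(
                aln.locus_id, {lab: aln.rows.get(lab, gap_row) for lab in labels}
            )
            mat, _ = encode_alignment(padded)
            mats.append(mat)
            self.locus_sites.append(aln.n_sites)
        big = np.hstack(mats)
        self.patterns, inverse = np.unique(big, axis=1, return_inverse=True)
        inverse = inverse.ravel()
        n_pat = self.patterns.shape[1]
        self.locus_weights = np.zeros((len(loci), n_pat))
        offset = 0
        for li, n in enumerate(self.locus_sites):
            seg = inverse[offset : offset + n]
            np.add.at(self.locus_weights[li], seg, 1.0)
            offset += n
        self.row_index = {lab: i for i, lab in enumerate(self.labels)}

    def weights_for(self, locus_indices: np.ndarray) -> np.ndarray:
        return self.locus_weights[locus_indices].sum(axis=0)

    def engine_for(
        self, tree: dendropy.Tree, weights: np.ndarray
    ) -> PruningEngine:
        nz = weights > 0
        return PruningEngine(
            tree, self.patterns[:, nz], weights[nz], self.row_index, self.model
        )


def genewise_bootstrap(
    loci_alignments: Sequence[AminoAlignment],
    fixed_topology: dendropy.Tree,
    model: SubstitutionModel,
    calibrations: Sequence[CalibrationConstraint],
    lam: float,
    n_replicates: int = 100,
    seed: int = 0,
    outgroup: str | None = None,
    dating_starts: int = 3,
    bl_tol: float = 1e-6,
    max_failure_frac: float = 0.10,
) -> AgeSampleTable:
    """Run the full gene-wise bootstrap and collect per-node age samples.

    Each replicate draws ``n_loci`` locus indices with replacement,
    re-optimizes branch lengths on ``fixed_topology`` (whose input lengths
    seed the optimizer), prunes *outgroup* if given, and dates with the same
    smoothing weight and calibrations. A replicate whose dating fails is
    retried with a fresh jitter seed; every failure is counted, and once
    failures exceed ``max_failure_frac`` of ``n_replicates`` the run errors.
    """
    if len(loci_alignments) < 2:
        raise InputError("gene-wise bootstrap needs at least 2 loci")
    labels = trees.leaf_labels(fixed_topology)
    rng = np.random.default_rng(seed)
    pooled = _ReplicateLikelihood(loci_alignments, labels, model)
    n_loci = len(loci_alignments)
    sites = np.array(pooled.locus_sites)

    samples: dict[frozenset, list[float]] = {}
    failures = 0
    max_failures = max(1, int(max_failure_frac * n_replicates))
    import zlib

    for rep in range(n_replicates):
        idx = rng.integers(n_loci, size=n_loci)
        rep_sites = int(sites[idx].sum())
        work = trees.clone(fixed_topology)
        weights = pooled.weights_for(idx)
        eng = pooled.engine_for(work, weights)
        optimize_branch_lengths(work, None, model, tol=bl_tol, engine=eng)
        # Dating seed derives from the replicate's data (and the run seed),
        # so byte-identical replicates date byte-identically.
        data_key = zlib.crc32(weights.tobytes())
        dated: Chronogram | None = None
        for _attempt in range(10):
            jitter_seed = (data_key ^ seed ^ (_attempt * 0x9E3779B1)) % 2**31
            to_date = prune_outgroup(work, outgroup) if outgroup else work
            try:
                dated = pl_date(
                    to_date, calibrations, lam, rep_sites,
                    n_starts=dating_starts, seed=jitter_seed,
                )
                break
            except CycadPhyloError as exc:
                failures += 1
                logger.warning("replicate %d dating failed (%s); retrying", rep, exc)
                if failures > max_failures:
                    raise CycadPhyloError(
                        f"bootstrap aborted: {failures} dating failures exceed "
                        f"{max_failure_frac:.0%} of {n_replicates} replicates"
                    ) from exc
        if dated is None:
            continue
        for node_tips, age in dated.ages.items():
            samples.setdefault(node_tips, []).append(age)
    return AgeSampleTable(samples, n_replicates)


# ---------------------------------------------------------------------------
# Reporting


def ci_report(
    table: AgeSampleTable,
    point_ages: dict[frozenset, float] | None = None,
    path: str | Path | None = None,
) -> tuple[list[dict], float]:
    """One row per node (bipartition hash, point age, lower, upper, width)
    plus the mean CI width; optionally written as TSV with a footer."""
    from .concordance import branch_key

    rows = []
    for node in table.nodes():
        lo, hi = table.ci(node)
        point = point_ages.get(node) if point_ages else None
        rows.append(
            {
                "node": branch_key(frozenset({node, frozenset()})),
                "tips": ",".join(sorted(node)),
                "point_age": point,
                "lower": lo,
                "upper": hi,
                "width": hi - lo,
            }
        )
    mean_width = float(np.mean([r["width"] for r in rows])) if rows else float("nan")
    if path is not None:
        with Path(path).open("w") as fh:
            fh.write("node\ttips\tpoint_age\tlower\tupper\twidth\n")
            for r in rows:
                pt = "NA" if r["point_age"] is None else f"{r['point_age']:.6g}"
                fh.write(
                    f"{r['node']}\t{r['tips']}\t{pt}\t{r['lower']:.6g}\t"
                    f"{r['upper']:.6g}\t{r['width']:.6g}\n"
                )
            fh.write(f"# mean_ci_width\t{mean_width:.6g}\n")
    return rows, mean_width
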