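"""Relaxed single-copy orthogroup filtering and paralog pruning.

The filter retains a locus when it is present in at least a given fraction
of accessions (default 75%) and at most a given fraction carry a second
copy (default 10%). The pruner resolves remaining multi-copy accessions on
the gene tree: for each accession with several copies, the copy with the
smallest average patristic distance to the tips of all *other* accessions
is kept — the phylogenetically closest copy, which preferentially selects
orthologs over deep paralogs — and the discarded copies' rows are dropped
from the locus alignment.

Conventions (documented because the thresholds admit two readings):

* the presence cutoff is ``ceil(min_presence_frac * n_accessions)``;
* the second-copy cutoff is, by default, ``floor(max_second_copy_frac *
  n_present)`` — relative to accessions present in the locus, so a sparse
  locus gains no duplicate headroom from absent accessions. Pass
  ``relative_to="all"`` to compute it against the full panel instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import trees
from .errors import ConsistencyError, InputError
from .phyloio import AminoAlignment

logger = logging.getLogger(__name__)


class OccupancyMatrix:
    """Per-locus copy counts (0/1/2+) for every accession."""

    def __init__(
        self,
        counts: np.ndarray,
        locus_ids: Sequence[str],
        accession_ids: Sequence[str],
    ):
        counts = np.asarray(counts, dtype=int)
        if counts.ndim != 2:
            raise InputError("occupancy counts must be a 2-D array")
        if counts.shape != (len(locus_ids), len(accession_ids)):
            raise InputError(
                f"occupancy shape {counts.shape} inconsistent with "
                f"{len(locus_ids)} loci x {len(accession_ids)} accessions"
            )
        if (counts < 0).any():
            raise InputError("copy counts must be >= 0")
        self.counts = counts
        self.locus_ids = list(locus_ids)
        self.accession_ids = list(accession_ids)

    @property
    def n_loci(self) -> int:
        return self.counts.shape[0]

    @property
    def n_accessions(self) -> int:
        return self.counts.shape[1]

    def mean_occupancy(self) -> float:
        """Mean over loci of the fraction of accessions present (>= 1 copy)."""
        return float((self.counts >= 1).mean(axis=1).mean())

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.counts, index=self.locus_ids, columns=self.accession_ids
        )
        df.index.name = "locus_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OccupancyMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), list(df.index.astype(str)), list(df.columns))


@dataclass(frozen=True)
class FilterDecision:
    locus_id: str
    n_present: int
    n_multi_copy: int
    retained: bool
    reason: str


def filter_orthogroups(
    matrix: OccupancyMatrix,
    min_presence_frac: float = 0.75,
    max_second_copy_frac: float = 0.10,
    relative_to: str = "present",
) -> list[FilterDecision]:
    """Apply the relaxed single-copy filter to every locus.

    A locus is retained iff ``n_present >= ceil(min_presence_frac *
    n_accessions)`` and ``n_multi_copy <= floor(max_second_copy_frac * base)``
    where ``base`` is ``n_present`` (default) or ``n_accessions``
    (``relative_to="all"``). Decisions are deterministic and invariant to
    row/column permutation of the matrix.
    """
    if not (0.0 <= min_presence_frac <= 1.0 and 0.0 <= max_second_copy_frac <= 1.0):
        raise InputError("filter fractions must lie in [0, 1]")
    if relative_to not in ("present", "all"):
        raise InputError("relative_to must be 'present' or 'all'")
    if matrix.n_loci == 0 or matrix.n_accessions == 0:
        raise InputError("occupancy matrix is empty")

    presence_cutoff = presence_threshold(matrix.n_accessions, min_presence_frac)
    decisions = []
    for i, locus_id in enumerate(matrix.locus_ids):
        row = matrix.counts[i]
        n_present = int((row >= 1).sum())
        n_multi = int((row >= 2).sum())
        base = n_present if relative_to == "present" else matrix.n_accessions
        multicopy_cutoff = math.floor(max_second_copy_frac * base)
        if n_present < presence_cutoff:
            retained, reason = False, (
                f"present in {n_present} < {presence_cutoff} accessions"
            )
        elif n_multi > multicopy_cutoff:
            retained, reason = False, (
                f"{n_multi} multi-copy accessions > cutoff {multicopy_cutoff}"
            )
        else:
            retained, reason = True, "passes presence and second-copy rules"
        decisions.append(
            FilterDecision(locus_id, n_present, n_multi, retained, reason)
        )
    return decisions


def presence_threshold(n_accessions: int, min_presence_frac: float = 0.75) -> int:
    """Minimum number of accessions a locus must appear in (ceiling rule)."""
    return math.ceil(min_presence_frac * n_accessions)


def decisions_to_tsv(decisions: Sequence[FilterDecision], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("locus_id\tn_present\tn_multi_copy\tretained\treason\n")
        for d in decisions:
            fh.write(
                f"{d.locus_id}\t{d.n_present}\t{d.n_multi_copy}\t"
                f"{int(d.retained)}\t{d.reason}\n"
            )


# ---------------------------------------------------------------------------
# Paralog pruning


def _accession_of(label: str) -> str:
    return label.split("__")[0]


@dataclass(frozen=True)
class PruneRecord:
    accession_id: str
    kept_label: str
    removed_labels: tuple[str, ...]
    kept_avg_distance: float
    tie: bool


def prune_paralogs(
    gene_tree: dendropy.Tree,
    alignment: AminoAlignment | None = None,
) -> tuple[dendropy.Tree, AminoAlignment | None, list[PruneRecord]]:
    """Collapse multi-copy accessions to their phylogenetically closest copy.

    Tip labels must be ``<accession_id>`` or ``<accession_id>__<k>``. For
    each accession with >= 2 tips, the patristic distance from each copy to
    every tip belonging to a *different* accession is averaged; the copy
    with the minimum average is kept (ties broken toward the
    lexicographically smaller label, logged) and relabeled to the bare
    accession id. Removed copies' rows are dropped from the alignment.
    """
    labels = trees.leaf_labels(gene_tree)
    if alignment is not None:
        diff = set(labels) ^ set(alignment.rows)
        if diff:
            raise ConsistencyError(
                f"tree/alignment label mismatch (symmetric difference): "
                f"{sorted(diff)}"
            )

    by_accession: dict[str, list[str]] = {}
    for lab in labels:
        by_accession.setdefault(_accession_of(lab), []).append(lab)
    multi = {acc: labs for acc, labs in by_accession.items() if len(labs) > 1}

    records: list[PruneRecord] = []
    if not multi:
        # nothing to prune; normalize any lone "__k" labels to bare ids
        out_tree = trees.clone(gene_tree)
        out_tree.locus_id = getattr(gene_tree, "locus_id", None)
        rename = {
            lab: _accession_of(lab) for lab in labels if lab != _accession_of(lab)
        }
        trees.relabel_tips(out_tree, rename)
        out_aln = alignment.relabel(rename) if alignment is not None else None
        return out_tree, out_aln, records

    dist = trees.patristic_distances(gene_tree)
    to_remove: list[str] = []
    rename: dict[str, str] = {}
    for acc in sorted(multi):
        copies = sorted(multi[acc])
        others = [lab for lab in labels if _accession_of(lab) != acc]
        averages = {
            c: sum(dist[(c, o)] for o in others) / len(others) for c in copies
        }
        best = min(averages.values())
        winners = sorted(c for c, a in averages.items() if a <= best + 0.0)
        kept = winners[0]
        tie = len(winners) > 1
        if tie:
            logger.info(
                "locus %s, accession %s: tie on average distance; keeping %s",
                getattr(gene_tree, "locus_id", "?"), acc, kept,
            )
        removed = tuple(c for c in copies if c != kept)
        to_remove.extend(removed)
        rename[kept] = acc
        records.append(PruneRecord(acc, kept, removed, averages[kept], tie))

    out_tree = trees.prune_tips(gene_tree, to_remove)
    out_tree.locus_id = getattr(gene_tree, "locus_id", None)
    rename.update(
        {
            lab: _accession_of(lab)
            for lab in trees.leaf_labels(out_tree)
            if lab != _accession_of(lab) and lab not in rename
        }
    )
    trees.relabel_tips(out_tree, rename)
    out_aln = None
    if alignment is not None:
        out_aln = alignment.subset(
            [lab for lab in alignment.rows if lab not in to_remove]
        ).relabel(rename)
    return out_tree, out_aln, records


def prune_report_tsv(records: Sequence[PruneRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("accession_id\tkept_label\tremoved_labels\tkept_avg_distance\ttie\n")
        for r in records:
            fh.write(
                f"{r.accession_id}\t{r.kept_label}\t{','.join(r.removed_labels)}\t"
                f"{r.kept_avg_distance:.9g}\t{int(r.tie)}\n"
            )
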