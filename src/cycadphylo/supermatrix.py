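"""Concatenation of pruned per-locus alignments into a partitioned supermatrix.

The row set is the union of accessions across loci; accessions absent from
a locus are filled with ``-`` across that locus's columns. Column order
follows locus order (lexicographic by locus id unless an explicit order is
given), and the partition scheme's boundaries equal the cumulative locus
lengths, 1-based inclusive.
"""

from __future__ import annotations

from typing import Sequence

from .errors import InputError
from .phyloio import AminoAlignment, PartitionScheme


def concatenate(
    alignments: Sequence[AminoAlignment],
    locus_order: Sequence[str] | None = None,
) -> tuple[AminoAlignment, PartitionScheme]:
    """Build the supermatrix and its partition scheme.

    Each input alignment must have at most one row per accession (prune
    paralogs first); a label of the form ``<id>__<k>`` is rejected with a
    pointer to the pruning step.
    """
    if not alignments:
        raise InputError("no alignments to concatenate")
    by_id = {a.locus_id: a for a in alignments}
    if len(by_id) != len(alignments):
        raise InputError("duplicate locus ids among alignments")
    if locus_order is None:
        order = sorted(by_id)
    else:
        missing = set(locus_order) ^ set(by_id)
        if missing:
            raise InputError(f"locus order does not match alignments: {sorted(missing)}")
        order = list(locus_order)

    for a in alignments:
        for label in a.rows:
            if "__" in label:
                raise InputError(
                    f"locus {a.locus_id!r} row {label!r} looks like an "
                    "unpruned gene copy; run paralog pruning before "
                    "concatenation"
                )

    accessions = sorted({label for a in alignments for label in a.rows})
    chunks: dict[str, list[str]] = {acc: [] for acc in accessions}
    ranges: list[tuple[str, int, int]] = []
    pos = 1
    for locus_id in order:
        a = by_id[locus_id]
        gap_fill = "-" * a.n_sites
        for acc in accessions:
            chunks[acc].append(a.rows.get(acc, gap_fill))
        ranges.append((locus_id, pos, pos + a.n_sites - 1))
        pos += a.n_sites

    rows = {acc: "".join(chunks[acc]) for acc in accessions}
    return AminoAlignment("supermatrix", rows), PartitionScheme(tuple(ranges))


def extract_partition(
    supermatrix: AminoAlignment, scheme: PartitionScheme, locus_id: str
) -> AminoAlignment:
    """Recover one locus's columns (rows that are all-gap are dropped,
    mirroring that accession's absence from the original locus)."""
    for name, start, end in scheme.ranges:
        if name == locus_id:
            rows = {}
            for label, seq in supermatrix.rows.items():
                piece = seq[start - 1 : end]
                if set(piece) != {"-"}:
                    rows[label] = piece
            return AminoAlignment(locus_id, rows)
    raise InputError(f"locus {locus_id!r} not in partition scheme")


def occupancy_summary(
    alignments: Sequence[AminoAlignment],
) -> tuple[dict[str, float], float]:
    """Per-locus occupancy (rows present / union size) and the mean over loci.

    Percentages are on 0-100; the mean is conventionally reported to 0.1%.
    """
    if not alignments:
        return {}, float("nan")
    union = {label for a in alignments for label in a.rows}
    per_locus = {
        a.locus_id: 100.0 * len(a.rows) / len(union) for a in alignments
    }
    mean = sum(per_locus.values()) / len(per_locus)
    return per_locus, mean
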