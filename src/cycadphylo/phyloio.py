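"""Readers and writers for every external format the pipeline touches.

Formats: FASTA amino-acid alignments, Newick trees (with slash-separated
internal-node annotation strings preserved verbatim), RAxML-style partition
files, and TSV tables for calibrations, occupancy matrices, and
accession-to-taxon-name sidecars.

Conventions
-----------
* Tip labels in Newick/FASTA are accession ids; a sidecar TSV maps
  accession_id -> taxon_name, so the same accepted species name may appear
  on more than one terminal without breaking label uniqueness.
* Gap character is ``-``; ``?`` is normalized to ``-`` on read (warning).
* Partition coordinates are 1-based inclusive (RAxML dialect).
* All writers are deterministic given identical inputs.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    CalibrationError,
    InputError,
    NewickParseError,
    PartitionSchemeError,
    TreeValidationError,
)

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Full row alphabet: amino acids, ambiguity X, gap.
ALPHABET = frozenset(AMINO_ACIDS) | {"X", "-"}

_NEWICK_RESERVED = set("(),:;'") | {" ", "\t", "\n", "\r"}


def validate_accession_id(accession_id: str) -> None:
    """Raise InputError unless *accession_id* is usable as a tip label."""
    if not accession_id:
        raise InputError("accession_id must be non-empty")
    bad = sorted(set(accession_id) & _NEWICK_RESERVED)
    if bad:
        raise InputError(
            f"accession_id {accession_id!r} contains reserved characters: {bad}"
        )


@dataclass(frozen=True)
class Accession:
    """A sequenced terminal: unique id plus free-text taxon name."""

    accession_id: str
    taxon_name: str

    def __post_init__(self) -> None:
        validate_accession_id(self.accession_id)


class AminoAlignment:
    """Labeled, equal-length amino-acid sequences for one locus (or the supermatrix).

    Rows are held as an ordered mapping tip-label -> sequence string over
    the alphabet {20 amino-acid letters, X, -}, case-folded to upper.
    """

    __slots__ = ("locus_id", "rows", "n_sites")

    def __init__(self, locus_id: str, rows: Mapping[str, str]):
        if not rows:
            raise InputError(f"alignment {locus_id!r} has no records")
        clean: dict[str, str] = {}
        n_sites = None
        for label, seq in rows.items():
            if label in clean:
                raise AlignmentShapeError(
                    f"alignment {locus_id!r}: duplicate label {label!r}"
                )
            seq = seq.upper()
            if "?" in seq:
                logger.warning(
                    "alignment %s, record %s: '?' normalized to '-'", locus_id, label
                )
                seq = seq.replace("?", "-")
            if n_sites is None:
                n_sites = len(seq)
            elif len(seq) != n_sites:
                raise AlignmentShapeError(
                    f"alignment {locus_id!r}: record {label!r} has length "
                    f"{len(seq)}, expected {n_sites}"
                )
            for pos, ch in enumerate(seq):
                if ch not in ALPHABET:
                    raise AlphabetError(
                        f"alignment {locus_id!r}: record {label!r} has illegal "
                        f"character {ch!r} at position {pos + 1}"
                    )
            clean[label] = seq
        if n_sites == 0:
            raise AlignmentShapeError(f"alignment {locus_id!r} has zero sites")
        self.locus_id = locus_id
        self.rows = clean
        self.n_sites = n_sites

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AminoAlignment)
            and self.locus_id == other.locus_id
            and self.rows == other.rows
        )

    def labels(self) -> list[str]:
        return list(self.rows)

    def subset(self, labels: Iterable[str]) -> "AminoAlignment":
        """Alignment restricted to *labels*, preserving this alignment's order."""
        keep = set(labels)
        missing = keep - set(self.rows)
        if missing:
            raise InputError(
                f"alignment {self.locus_id!r} lacks rows: {sorted(missing)}"
            )
        return AminoAlignment(
            self.locus_id, {k: v for k, v in self.rows.items() if k in keep}
        )

    def relabel(self, mapping: Mapping[str, str]) -> "AminoAlignment":
        """Rename rows via *mapping* (labels absent from it are kept)."""
        return AminoAlignment(
            self.locus_id, {mapping.get(k, k): v for k, v in self.rows.items()}
        )


@dataclass(frozen=True)
class CalibrationConstraint:
    """Min/max age bounds (Ma) on the MRCA of a pair of tips."""

    label: str
    tip_a: str
    tip_b: str
    min_ma: float
    max_ma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_ma <= self.max_ma):
            raise CalibrationError(
                f"calibration {self.label!r}: need 0 <= min <= max, "
                f"got ({self.min_ma}, {self.max_ma})"
            )


@dataclass(frozen=True)
class PartitionScheme:
    """Ordered contiguous 1-based inclusive ranges covering 1..total_sites."""

    ranges: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not self.ranges:
            raise PartitionSchemeError("empty partition scheme")
        expected_start = 1
        for name, start, end in self.ranges:
            if start != expected_start:
                raise PartitionSchemeError(
                    f"partition {name!r} starts at {start}, expected "
                    f"{expected_start} (gap or overlap)"
                )
            if end < start:
                raise PartitionSchemeError(
                    f"partition {name!r} has end {end} < start {start}"
                )
            expected_start = end + 1

    @property
    def total_sites(self) -> int:
        return self.ranges[-1][2]

    def locus_ids(self) -> list[str]:
        return [name for name, _, _ in self.ranges]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, locus_id: str | None = None) -> AminoAlignment:
    """Read one FASTA alignment; record order is preserved.

    Raises AlignmentShapeError for ragged rows, AlphabetError for characters
    outside the amino-acid alphabet. Windows line endings are accepted.
    """
    path = Path(path)
    rows: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        rows[record.id] = str(record.seq)
    if not rows:
        raise InputError(f"{path}: no FASTA records")
    return AminoAlignment(locus_id or path.stem, rows)


def write_fasta(alignment: AminoAlignment, path: str | Path, width: int = 80) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for label, seq in alignment.rows.items():
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick


def _validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    seen: set[str] = set()
    for lab in labels:
        if lab is None or lab == "":
            raise TreeValidationError("tree has an unlabeled tip")
        if lab in seen:
            raise TreeValidationError(f"duplicate tip label {lab!r}")
        seen.add(lab)
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            continue
        if not math.isfinite(edge.length) or edge.length < 0:
            raise TreeValidationError(
                f"branch length {edge.length!r} is not finite and >= 0"
            )
    return tree


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string into a validated dendropy Tree."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        msg = str(exc)
        if "uplicate" in msg or "multiple" in msg.lower():
            raise TreeValidationError(f"duplicate tip label: {msg}") from exc
        offset = newick.find("(")
        raise NewickParseError(f"Newick parse failed: {msg} (input starts at "
                               f"offset {offset})") from exc
    tree.is_rooted = True
    return _validate_tree(tree)


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single Newick tree from *path*."""
    text = Path(path).read_text()
    if not text.strip():
        raise NewickParseError(f"{path}: empty file")
    return parse_newick(text)


def read_newick_list(path: str | Path) -> list[dendropy.Tree]:
    """Read one Newick tree per line (blank lines skipped)."""
    trees = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            trees.append(parse_newick(line))
    return trees


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Serialize with enough digits that read-back branch lengths differ by
    < 1e-9 relative error; internal-node labels written verbatim."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    )
    return s.strip() + "\n"


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree))


def write_newick_list(trees: Sequence[dendropy.Tree], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for tree in trees:
            fh.write(tree_to_newick(tree))


# ---------------------------------------------------------------------------
# RAxML-style partition files

_PARTITION_RE = re.compile(
    r"^\s*AA\s*,\s*(?P<name>\S+)\s*=\s*(?P<start>\d+)\s*-\s*(?P<end>\d+)\s*$"
)


def read_partitions(path: str | Path) -> PartitionScheme:
    """Read 'AA, <name> = <start>-<end>' lines (1-based inclusive)."""
    ranges: list[tuple[str, int, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        m = _PARTITION_RE.match(line)
        if m is None:
            raise PartitionSchemeError(
                f"{path}, line {lineno}: cannot parse partition line {line!r}"
            )
        ranges.append((m["name"], int(m["start"]), int(m["end"])))
    return PartitionScheme(tuple(ranges))


def write_partitions(scheme: PartitionScheme, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, start, end in scheme.ranges:
            fh.write(f"AA, {name} = {start}-{end}\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_calibrations(path: str | Path) -> list[CalibrationConstraint]:
    """Read a calibration TSV with columns
    node_label, tip_a, tip_b, min_ma, max_ma (header required)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = ["node_label", "tip_a", "tip_b", "min_ma", "max_ma"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CalibrationError(f"{path}: missing columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                CalibrationConstraint(
                    label=str(row["node_label"]),
                    tip_a=str(row["tip_a"]),
                    tip_b=str(row["tip_b"]),
                    min_ma=float(row["min_ma"]),
                    max_ma=float(row["max_ma"]),
                )
            )
        except CalibrationError as exc:
            raise CalibrationError(f"{path}, row {i + 1}: {exc}") from exc
    return out


def write_calibrations(
    calibrations: Sequence[CalibrationConstraint], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("node_label\ttip_a\ttip_b\tmin_ma\tmax_ma\n")
        for c in calibrations:
            fh.write(f"{c.label}\t{c.tip_a}\t{c.tip_b}\t{c.min_ma:g}\t{c.max_ma:g}\n")


def read_accession_table(path: str | Path) -> list[Accession]:
    """Sidecar TSV mapping accession_id -> taxon_name (two columns, header)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    accs = [
        Accession(str(r["accession_id"]), str(r["taxon_name"]))
        for _, r in df.iterrows()
    ]
    ids = [a.accession_id for a in accs]
    if len(set(ids)) != len(ids):
        raise InputError(f"{path}: duplicate accession ids")
    return accs


def write_accession_table(accessions: Sequence[Accession], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("accession_id\ttaxon_name\n")
        for a in accessions:
            fh.write(f"{a.accession_id}\t{a.taxon_name}\n")
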