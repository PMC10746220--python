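"""Readers and writers for the plain-text formats the toolkit consumes.

Every downstream module operates on in-memory objects produced here:
FASTA contig collections, per-locus GFF3 exon tracks, labelled numeric
matrices from TSV, and newick trees with branch lengths.  All genomic
coordinates are 1-based inclusive (the GFF3 convention); any half-open
caller must convert at this boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class TableSpec:
    """Declarative description of a required TSV layout.

    ``required_columns`` maps column name to a semantic type tag, one of
    ``"str"``, ``"int"``, ``"float"``.  ``permit_missing`` lists columns in
    which NA markers are tolerated (they become NaN).
    """

    name: str
    required_columns: tuple[tuple[str, str], ...]
    delimiter: str = "\t"
    permit_missing: frozenset[str] = frozenset()


@dataclass
class SequenceCollection:
    """An ordered set of named sequences with pre-computed lengths."""

    records: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def identifiers(self) -> list[str]:
        return [r[0] for r in self.records]

    def lengths(self) -> dict[str, int]:
        return {r[0]: r[2] for r in self.records}

    def __len__(self) -> int:
        return len(self.records)


def read_fasta(path: str | Path) -> SequenceCollection:
    """Read a FASTA file into a :class:`SequenceCollection`.

    Record order is preserved; wrapped and unwrapped sequence lines are
    equivalent.  An empty file or a duplicated header is an error.
    """
    path = Path(path)
    records: list[tuple[str, str, int]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA header: {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        records.append((rec.id, seq, len(seq)))
    if not records:
        raise FormatError(f"empty or headerless FASTA file: {path}")
    return SequenceCollection(records)


def write_fasta(collection: SequenceCollection, path: str | Path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq, _ in collection.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# GFF3 exon tracks
# ---------------------------------------------------------------------------

_GFF3_COLUMNS = (
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
)


def _parse_gff3_attributes(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in raw.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF3 attribute field: {part!r}")
        key, value = part.split("=", 1)
        out[key] = value
    return out


def read_gff3_exons(
    path: str | Path, track_label: str | None = None
) -> dict[str, list[dict]]:
    """Group exon/CDS features of a GFF3 file by their Parent locus.

    Returns ``{locus_id: [exon, ...]}`` where each exon is a dict with keys
    ``contig, start, end, strand, source`` and coordinates kept 1-based
    inclusive exactly as read.  Exons within a locus are sorted by start.
    If ``track_label`` is given, only rows whose GFF3 source column equals
    it are read (used to separate ab initio from protein-evidence tracks
    stored in one file).
    """
    path = Path(path)
    loci: dict[str, list[dict]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-delimited GFF3 columns, got {len(fields)}"
                )
            row = dict(zip(_GFF3_COLUMNS, fields))
            if row["type"].lower() not in ("exon", "cds"):
                continue
            if track_label is not None and row["source"] != track_label:
                continue
            attrs = _parse_gff3_attributes(row["attributes"])
            parent = attrs.get("Parent") or attrs.get("parent")
            if parent is None:
                raise FormatError(
                    f"{path}:{lineno}: exon/CDS feature lacks a Parent attribute"
                )
            start, end = int(row["start"]), int(row["end"])
            if end < start:
                raise FormatError(
                    f"{path}:{lineno}: end ({end}) < start ({start})"
                )
            loci.setdefault(parent, []).append(
                {
                    "contig": row["seqid"],
                    "start": start,
                    "end": end,
                    "strand": row["strand"],
                    "source": row["source"],
                }
            )
    for exons in loci.values():
        exons.sort(key=lambda e: (e["start"], e["end"]))
    return loci


def write_gff3_exons(
    loci: dict[str, Sequence[dict]], path: str | Path, feature_type: str = "exon"
) -> None:
    """Write per-locus exon dicts back to GFF3 (inverse of read_gff3_exons)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus_id in loci:
            for e in loci[locus_id]:
                fh.write(
                    "\t".join(
                        [
                            e["contig"],
                            e.get("source", "eukmag"),
                            feature_type,
                            str(e["start"]),
                            str(e["end"]),
                            ".",
                            e["strand"],
                            ".",
                            f"Parent={locus_id}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Labelled numeric matrices
# ---------------------------------------------------------------------------

def read_matrix_tsv(
    path: str | Path,
    spec: TableSpec | None = None,
    permit_missing: bool = False,
    delimiter: str = "\t",
) -> pd.DataFrame:
    """Read a labelled numeric matrix: header of column labels, first
    column = row labels, all remaining cells numeric.

    ``permit_missing`` (or a spec whose ``permit_missing`` is non-empty)
    allows NA/empty cells, which become NaN; otherwise any missing or
    non-numeric cell is an error naming its row and column.
    """
    if spec is not None:
        delimiter = spec.delimiter
        permit_missing = permit_missing or bool(spec.permit_missing)
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate row label {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate column label {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    is_na_marker = df.isna() | (df == "NA") | (df == "")
    bad = numeric.isna() & (~is_na_marker if permit_missing else True)
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise FormatError(
            f"{path}: non-numeric or missing cell at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    numeric.index.name = df.index.name
    return numeric


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    df.to_csv(path, sep=delimiter, na_rep="NA")


def read_table(path: str | Path, spec: TableSpec) -> pd.DataFrame:
    """Read a long-format table, enforcing a :class:`TableSpec`.

    Required columns must each be present exactly once; cells are coerced
    to the spec's semantic type, with errors naming the offending cell.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=spec.delimiter, dtype=str)
    for col, kind in spec.required_columns:
        matches = [c for c in df.columns if c == col]
        if len(matches) != 1:
            raise FormatError(
                f"{path}: table {spec.name!r} requires column {col!r} exactly once "
                f"(found {len(matches)})"
            )
        if kind in ("int", "float"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if col in spec.permit_missing:
                bad &= df[col] != "NA"
            if bad.any():
                i = int(np.argwhere(bad.values)[0][0])
                raise FormatError(
                    f"{path}: non-numeric value {df[col].iloc[i]!r} in column "
                    f"{col!r}, row {i + 2}"
                )
            missing = df[col].isna()
            if missing.any() and col not in spec.permit_missing:
                i = int(np.argwhere(missing.values)[0][0])
                raise FormatError(f"{path}: missing value in column {col!r}, row {i + 2}")
            df[col] = coerced.astype(int) if kind == "int" and not coerced.isna().any() else coerced
    return df


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def read_newick(path_or_string: str | Path, *, is_string: bool = False) -> dendropy.Tree:
    """Read a newick tree, requiring branch lengths on every non-root edge
    (phylogenetic diversity is undefined without them) and unique leaf labels.
    """
    try:
        if is_string:
            tree = dendropy.Tree.get(data=str(path_or_string), schema="newick")
        else:
            tree = dendropy.Tree.get(path=str(path_or_string), schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise FormatError(f"duplicate leaf label in tree: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({x for x in labels if labels.count(x) > 1})[0]
        raise FormatError(f"duplicate leaf label {dup!r} in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root edge may legitimately lack a length
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon else "<internal>"
            raise FormatError(
                f"edge above node {name!r} has no branch length; "
                "branch lengths are required"
            )
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def total_tree_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths.  The root edge is excluded except in the
    degenerate single-node tree, whose only length lives on that edge."""
    internal = sum(
        e.length or 0.0
        for e in tree.preorder_edge_iter()
        if e.head_node is not tree.seed_node
    )
    if internal == 0.0 and len(tree.leaf_nodes()) == 1:
        return tree.seed_node.edge.length or 0.0
    return internal
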