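"""Readers and writers: labeled FASTA, Newick with supports, TSV reports.

FASTA header dialect::

    >ACCESSION species=Genus_species [marker=NAME]

The species tag is mandatory (it carries the accession -> species map);
the marker tag is optional and defaults to the marker name passed by the
caller.  Newick trees are handled by dendropy; bootstrap supports are
stored as integer internal-node labels, the dominant convention.
"""

from __future__ import annotations

import os
import re
from typing import Iterable, Mapping

import dendropy

from .alignments import MarkerAlignment, SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "newick_string",
    "tree_from_newick",
    "support_of",
    "write_tsv",
    "FastaParseError",
    "NewickParseError",
]


class FastaParseError(ValueError):
    """Malformed FASTA input; message carries the 1-based line number."""


class NewickParseError(ValueError):
    """Malformed Newick input."""


_HEADER_RE = re.compile(r"^>(?P<acc>\S+)(?P<rest>.*)$")
_TAG_RE = re.compile(r"(\w+)=(\S+)")


def read_fasta(path: str | os.PathLike, marker: str) -> MarkerAlignment:
    """Read one marker's alignment from a labeled FASTA file.

    Raises :class:`FastaParseError` (with the offending line number) on
    malformed headers, and :class:`AlignmentError` on ragged lengths or
    duplicate accessions.
    """
    records: list[SequenceRecord] = []
    acc = species = None
    rec_marker = marker
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal acc, species, chunks, rec_marker
        if acc is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"line {line_no}: record {acc!r} has no sequence data"
            )
        records.append(SequenceRecord(acc, species, rec_marker, seq))
        acc = species = None
        chunks = []

    with open(path, "rt", encoding="utf-8") as handle:
        line_no = 0
        for line_no, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                m = _HEADER_RE.match(line)
                if m is None:
                    raise FastaParseError(f"line {line_no}: malformed header {line!r}")
                tags = dict(_TAG_RE.findall(m.group("rest")))
                if "species" not in tags:
                    raise FastaParseError(
                        f"line {line_no}: header {line!r} lacks a species=... tag"
                    )
                acc = m.group("acc")
                species = tags["species"]
                rec_marker = tags.get("marker", marker)
                chunks = []
            else:
                if acc is None:
                    raise FastaParseError(
                        f"line {line_no}: sequence data before first header"
                    )
                chunks.append(line)
        flush(line_no)

    if not records:
        raise FastaParseError("empty FASTA file")
    return MarkerAlignment(marker=marker, records=records)


def write_fasta(alignment: MarkerAlignment, path: str | os.PathLike) -> None:
    """Write an alignment in the labeled FASTA dialect (60-column wrap)."""
    with open(path, "wt", encoding="utf-8") as handle:
        for rec in alignment:
            handle.write(f">{rec.accession_id} species={rec.species}\n")
            for i in range(0, len(rec.residues), 60):
                handle.write(rec.residues[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Newick


def support_of(node: dendropy.Node) -> int | None:
    """Bootstrap support stored as this internal node's label, if any."""
    if node.label is None:
        return None
    try:
        return int(round(float(node.label)))
    except (TypeError, ValueError):
        return None


def tree_from_newick(text: str, rooted: bool | None = None) -> dendropy.Tree:
    """Parse a Newick string into a dendropy Tree.

    Internal-node labels are kept verbatim (integer labels are read back
    as bootstrap supports by :func:`support_of`).
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    if rooted is not None:
        tree.is_rooted = rooted
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise NewickParseError("duplicate leaf labels in Newick input")
    return tree


def read_newick(path: str | os.PathLike, rooted: bool | None = None) -> dendropy.Tree:
    with open(path, "rt", encoding="utf-8") as handle:
        return tree_from_newick(handle.read(), rooted=rooted)


def newick_string(tree: dendropy.Tree) -> str:
    """Serialize with supports as internal-node labels, 12-digit lengths."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    ).strip()


def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write(newick_string(tree) + "\n")


# ---------------------------------------------------------------------------
# TSV reports (UTF-8, tab-separated, header row, '.' decimal)


def write_tsv(
    path: str | os.PathLike,
    header: Iterable[str],
    rows: Iterable[Iterable[object]],
) -> None:
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write("\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")
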