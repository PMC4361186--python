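"""Aligned-sequence containers for multi-marker barcode datasets.

A dataset is a set of per-marker multiple sequence alignments (one
alignment per barcoding locus, e.g. rbcL / matK / trnH-psbA / trnL-F /
ITS) plus a single accession -> species map shared across markers.
Accession sets may differ between markers; concatenation gap-fills the
missing blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "IUPAC_CHARS",
    "SequenceRecord",
    "MarkerAlignment",
    "MultiMarkerDataset",
    "concatenate_markers",
]

# Unambiguous bases, IUPAC ambiguity codes, and the gap character.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")


class AlignmentError(ValueError):
    """Raised for ragged alignments, bad residues or duplicate ids."""


def _normalize_residues(residues: str, accession_id: str) -> str:
    seq = residues.upper().replace("U", "T")
    bad = set(seq) - IUPAC_CHARS
    if bad:
        raise AlignmentError(
            f"record {accession_id!r}: invalid residue(s) {sorted(bad)!r}"
        )
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence: an accession of a species at one marker.

    Residues are normalized to uppercase with U mapped to T; only
    A/C/G/T, IUPAC ambiguity codes and ``-`` are accepted.
    """

    accession_id: str
    species: str
    marker: str
    residues: str

    def __post_init__(self) -> None:
        if not self.accession_id:
            raise AlignmentError("accession_id must be non-empty")
        if not self.residues:
            raise AlignmentError(f"record {self.accession_id!r}: empty sequence")
        object.__setattr__(
            self, "residues", _normalize_residues(self.residues, self.accession_id)
        )


@dataclass
class MarkerAlignment:
    """An MSA for a single marker: equal-length records, unique ids.

    ``blocks`` is populated by :func:`concatenate_markers` with the
    ``(marker, start, stop)`` column spans of each source alignment.
    """

    marker: str
    records: list[SequenceRecord]
    blocks: list[tuple[str, int, int]] | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError(f"marker {self.marker!r}: alignment has no records")
        length = len(self.records[0].residues)
        seen: set[str] = set()
        for rec in self.records:
            if len(rec.residues) != length:
                raise AlignmentError(
                    f"marker {self.marker!r}: record {rec.accession_id!r} has "
                    f"length {len(rec.residues)}, expected {length}"
                )
            if rec.accession_id in seen:
                raise AlignmentError(
                    f"marker {self.marker!r}: duplicate accession "
                    f"{rec.accession_id!r}"
                )
            seen.add(rec.accession_id)

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def accession_ids(self) -> list[str]:
        return [rec.accession_id for rec in self.records]

    @property
    def species_of(self) -> dict[str, str]:
        return {rec.accession_id: rec.species for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, accession_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.accession_id == accession_id:
                return rec
        raise KeyError(accession_id)


@dataclass
class MultiMarkerDataset:
    """Per-marker alignments plus the shared accession -> species map."""

    alignments: dict[str, MarkerAlignment]
    species_of: dict[str, str]

    def __post_init__(self) -> None:
        if not self.alignments:
            raise AlignmentError("dataset must contain at least one marker")
        for marker, aln in self.alignments.items():
            if marker != aln.marker:
                raise AlignmentError(
                    f"marker key {marker!r} does not match alignment "
                    f"marker {aln.marker!r}"
                )
            missing = [a for a in aln.accession_ids if a not in self.species_of]
            if missing:
                raise AlignmentError(
                    f"marker {marker!r}: accessions without species label: "
                    f"{missing[:5]!r}"
                )

    @property
    def markers(self) -> list[str]:
        return list(self.alignments)

    @classmethod
    def from_alignments(cls, alignments: Iterable[MarkerAlignment]) -> "MultiMarkerDataset":
        by_marker: dict[str, MarkerAlignment] = {}
        species: dict[str, str] = {}
        for aln in alignments:
            if aln.marker in by_marker:
                raise AlignmentError(f"duplicate marker {aln.marker!r}")
            by_marker[aln.marker] = aln
            for rec in aln:
                prev = species.get(rec.accession_id)
                if prev is not None and prev != rec.species:
                    raise AlignmentError(
                        f"accession {rec.accession_id!r} labeled {prev!r} and "
                        f"{rec.species!r} in different markers"
                    )
                species[rec.accession_id] = rec.species
        return cls(by_marker, species)


def concatenate_markers(
    dataset: MultiMarkerDataset, markers: Sequence[str]
) -> MarkerAlignment:
    """Concatenate selected marker alignments into one supermatrix.

    One record per accession present in at least one selected marker
    (union policy); an accession missing a marker receives a full block
    of ``-`` for that marker.  Column spans of each block are recorded
    in the result's ``blocks`` attribute.
    """
    if not markers:
        raise ValueError("marker list must be non-empty")
    unknown = [m for m in markers if m not in dataset.alignments]
    if unknown:
        raise KeyError(f"unknown marker(s): {unknown!r}")

    # union of accessions, ordered by first appearance across markers
    accessions: list[str] = []
    seen: set[str] = set()
    for m in markers:
        for acc in dataset.alignments[m].accession_ids:
            if acc not in seen:
                seen.add(acc)
                accessions.append(acc)

    blocks: list[tuple[str, int, int]] = []
    start = 0
    parts: dict[str, list[str]] = {acc: [] for acc in accessions}
    for m in markers:
        aln = dataset.alignments[m]
        blocks.append((m, start, start + aln.length))
        start += aln.length
        by_acc = {rec.accession_id: rec.residues for rec in aln}
        fill = "-" * aln.length
        for acc in accessions:
            parts[acc].append(by_acc.get(acc, fill))

    name = "+".join(markers)
    records = [
        SequenceRecord(acc, dataset.species_of[acc], name, "".join(parts[acc]))
        for acc in accessions
    ]
    return MarkerAlignment(marker=name, records=records, blocks=blocks)
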