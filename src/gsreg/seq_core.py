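"""Sequence and alignment handling with reference-anchored position mapping.

Glutamine-synthetase regulation prediction works in a fixed residue
numbering -- that of the *Methanothermococcus thermolithotrophicus* enzyme
(MtGS) -- while the sequences under study live in a multiple alignment.
This module provides the plumbing that every downstream stage relies on:
FASTA / aligned-FASTA I/O, and the mapping from reference residue numbers
to alignment columns so that "position 88" means the same thing in every
row of the alignment.

Conventions
-----------
* Residue positions and alignment columns are both 1-based, matching
  crystallographic residue numbering.
* The gap character is ``-``; ``.`` is accepted on read and normalised.
* Characters outside the 20 one-letter amino-acid codes are mapped to
  ``X`` (unknown) with a logged warning, never silently dropped.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The twenty standard one-letter amino-acid codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Residue alphabet accepted in unaligned sequences.
ALPHABET = frozenset(AA20) | {"X"}
#: Gap character used in alignments.
GAP = "-"

Source = Union[str, Path, TextIO]


class SequenceError(ValueError):
    """Malformed sequence input (bad alphabet, duplicate ids, ragged rows...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """An unaligned protein sequence.

    ``id`` is the FASTA identifier up to the first whitespace; the
    remainder of the header line is kept as ``description``.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise SequenceError(f"empty sequence for id {self.id!r}")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise SequenceError(
                f"invalid residue characters {sorted(bad)} in sequence {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignedRecord:
    """One gapped row of a multiple sequence alignment."""

    id: str
    residues: str
    description: str = ""

    def degap(self) -> SequenceRecord:
        return SequenceRecord(
            id=self.id,
            residues=self.residues.replace(GAP, ""),
            description=self.description,
        )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment: ordered rows of identical length."""

    records: tuple[AlignedRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise SequenceError("alignment has no rows")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            ncol = len(self.records[0])
            ragged = [r.id for r in self.records if len(r) != ncol]
            raise SequenceError(f"ragged alignment rows: {ragged}")
        ids = [r.id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SequenceError(f"duplicate ids in alignment: {sorted(dupes)}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def row(self, seq_id: str) -> AlignedRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(f"sequence id {seq_id!r} not in alignment")

    def __contains__(self, seq_id: str) -> bool:
        return any(r.id == seq_id for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class PositionMap:
    """Mapping from reference residue numbers to alignment columns (both 1-based)."""

    reference_id: str
    entries: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pos = [p for p, _ in self.entries]
        col = [c for _, c in self.entries]
        if pos != sorted(set(pos)) or col != sorted(set(col)):
            raise ValueError("PositionMap entries must be strictly increasing")

    def column(self, position: int) -> int:
        for p, c in self.entries:
            if p == position:
                return c
        raise KeyError(f"reference position {position} not mapped")

    @property
    def positions(self) -> list[int]:
        return [p for p, _ in self.entries]


# ---------------------------------------------------------------------------
# I/O


def _as_handle(source: Source) -> TextIO:
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.exists():
            return p.open()
        if isinstance(source, str) and source.lstrip().startswith(">"):
            return io.StringIO(source)
        raise FileNotFoundError(source)
    return source


def _normalize(raw: str, seq_id: str, aligned: bool) -> str:
    seq = raw.upper().replace(".", GAP)
    allowed = ALPHABET | ({GAP} if aligned else set())
    out = []
    mapped: set[str] = set()
    for ch in seq:
        if ch in allowed:
            out.append(ch)
        elif ch == GAP:
            raise SequenceError(
                f"gap character in unaligned sequence {seq_id!r}"
            )
        else:
            mapped.add(ch)
            out.append("X")
    if mapped:
        logger.warning(
            "sequence %s: mapped non-standard characters %s to 'X'",
            seq_id, sorted(mapped),
        )
    return "".join(out)


def _parse_fasta(source: Source, aligned: bool) -> list[tuple[str, str, str]]:
    handle = _as_handle(source)
    entries = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        entries.append((rec.id, _normalize(str(rec.seq), rec.id, aligned), desc))
    if not entries:
        raise SequenceError("no FASTA records in input")
    return entries


def read_fasta(source: Source) -> list[SequenceRecord]:
    """Read unaligned FASTA into :class:`SequenceRecord` objects.

    Residues are uppercased; characters outside the amino-acid alphabet
    are replaced by ``X`` with a warning; gap characters are an error.
    """
    return [SequenceRecord(i, s, d) for i, s, d in _parse_fasta(source, aligned=False)]


def read_msa(source: Source) -> Msa:
    """Read an aligned FASTA (equal-length gapped rows) into an :class:`Msa`."""
    return Msa(tuple(
        AlignedRecord(i, s, d) for i, s, d in _parse_fasta(source, aligned=True)
    ))


def _format_fasta(records: Iterable, width: int = 60) -> str:
    chunks = []
    for r in records:
        header = f">{r.id}" + (f" {r.description}" if r.description else "")
        body = "\n".join(
            r.residues[i:i + width] for i in range(0, len(r.residues), width)
        )
        chunks.append(f"{header}\n{body}\n")
    return "".join(chunks)


def write_fasta(records: Sequence[SequenceRecord], dest: Union[str, Path, TextIO],
                width: int = 60) -> None:
    """Write FASTA with lines wrapped at ``width`` characters."""
    text = _format_fasta(records, width)
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


def write_msa(msa: Msa, dest: Union[str, Path, TextIO], width: int = 60) -> None:
    """Write an alignment as aligned FASTA."""
    text = _format_fasta(msa.records, width)
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


# ---------------------------------------------------------------------------
# Reference-anchored mapping


def map_reference_positions(msa: Msa, reference_id: str,
                            positions: Sequence[int]) -> PositionMap:
    """Map reference residue numbers onto alignment columns.

    Walks the gapped reference row counting non-gap characters; the
    column at which the running count reaches a requested residue number
    is that position's alignment column.
    """
    row = msa.row(reference_id)  # KeyError if absent
    wanted = sorted(set(positions))
    if wanted and wanted[0] < 1:
        raise ValueError("reference positions are 1-based (got < 1)")
    entries = []
    residue_no = 0
    it = iter(wanted)
    target = next(it, None)
    for col0, ch in enumerate(row.residues):
        if ch == GAP:
            continue
        residue_no += 1
        while target is not None and residue_no == target:
            entries.append((target, col0 + 1))
            target = next(it, None)
    if target is not None:
        raise ValueError(
            f"position {target} exceeds degapped length {residue_no} "
            f"of reference {reference_id!r}"
        )
    return PositionMap(reference_id=reference_id, entries=tuple(entries))


def residues_at(msa: Msa, pmap: PositionMap, seq_id: str) -> dict[int, str]:
    """Residues of ``seq_id`` at the mapped reference positions.

    Returns ``{reference position: residue}``; a gap in the subject row
    at a mapped column is returned as ``'-'``.
    """
    row = msa.row(seq_id)
    return {pos: row.residues[col - 1] for pos, col in pmap.entries}
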