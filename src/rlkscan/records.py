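"""Sequence records, alphabets and FASTA I/O.

Sequences are plain uppercase strings tagged with an alphabet (``nt`` or
``aa``).  Gap characters (``-``) are legal only when a file is read as an
alignment.  Parsing and writing go through :mod:`Bio.SeqIO`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

# IUPAC nucleotide codes -> the set of unambiguous bases they stand for
IUPAC_NT: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

NT_CHARS = frozenset(IUPAC_NT)
# The 20 standard amino acids plus ambiguity codes B, Z, X and stop '*'
AA_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYBZX*")

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad characters, duplicate ids)."""


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence over a declared alphabet.

    Parameters
    ----------
    id:
        Unique label within a collection.
    residues:
        Uppercase sequence string; ``-`` permitted only if ``aligned``.
    alphabet:
        ``"nt"`` or ``"aa"``.
    description:
        Free text carried along from the FASTA header.
    """

    id: str
    residues: str
    alphabet: str
    description: str = ""
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        if self.alphabet not in ("nt", "aa"):
            raise SequenceError(f"record {self.id!r}: unknown alphabet {self.alphabet!r}")
        allowed = NT_CHARS if self.alphabet == "nt" else AA_CHARS
        for pos, ch in enumerate(self.residues):
            if ch == "-":
                if self.aligned:
                    continue
                raise SequenceError(
                    f"record {self.id!r}: gap character at position {pos} outside an alignment"
                )
            if ch not in allowed:
                raise SequenceError(
                    f"record {self.id!r}: illegal {self.alphabet} character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def reverse_complement(self) -> "SeqRecord":
        if self.alphabet != "nt":
            raise SequenceError(f"record {self.id!r}: cannot reverse-complement {self.alphabet}")
        return SeqRecord(
            id=self.id,
            residues=self.residues.translate(_COMPLEMENT)[::-1],
            alphabet="nt",
            description=self.description,
            aligned=self.aligned,
        )


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path, alphabet: str, aligned: bool = False) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    ``aligned=True`` permits ``-`` characters (alignment input).  Duplicate
    ids and illegal characters raise :class:`SequenceError`; an empty file
    yields an empty list with a logged warning.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise SequenceError(f"duplicate id {bio.id!r} in {path}")
        seen.add(bio.id)
        records.append(
            SeqRecord(
                id=bio.id,
                residues=str(bio.seq).upper(),
                alphabet=alphabet,
                description=bio.description,
                aligned=aligned,
            )
        )
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, wrap: int = 60) -> Path:
    """Write records to FASTA, ``wrap`` residues per line.  Round-trips with
    :func:`read_fasta`."""
    path = Path(path)
    bio_records = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap or None)
        writer.write_file(bio_records)
    return path


def require_unique_ids(records: Sequence[SeqRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise SequenceError(f"duplicate id {r.id!r}")
        seen.add(r.id)
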