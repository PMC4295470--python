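"""Alignments: containers, pairwise alignment statistics and protein→codon
back-translation.

Pairwise alignment follows the EMBOSS convention used throughout the
pairwise-identity tables of the analysis: BLOSUM62, gap open 10, gap extend
0.5 (the open cost is charged on the first gap residue), and identity /
similarity / gap percentages are computed over the full alignment length
including gap columns.  Similarity counts identities plus columns whose
substitution score is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import AlignIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .records import SeqRecord, SequenceError, require_unique_ids

logger = logging.getLogger(__name__)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

# codon -> amino acid for the standard nuclear code; stops map to '*'
STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(STANDARD_TABLE.forward_table)
for _stop in STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
SENSE_CODONS: tuple[str, ...] = tuple(sorted(STANDARD_TABLE.forward_table))
STOP_CODONS: frozenset[str] = frozenset(STANDARD_TABLE.stop_codons)


def translate_nt(seq: str) -> str:
    """Frame-0 translation; ambiguous codons become ``X``."""
    aa = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i: i + 3]
        aa.append(CODON_TO_AA.get(codon, "X"))
    return "".join(aa)


class AlignmentError(ValueError):
    """Raised for malformed alignments or back-translation mismatches."""


@dataclass(frozen=True)
class ProteinAlignment:
    """An aligned set of amino-acid records (equal lengths, ≥ 2 rows)."""

    records: tuple[SeqRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentError("alignment needs at least 2 records")
        require_unique_ids(self.records)
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal aligned lengths: {sorted(lengths)}")
        for r in self.records:
            if r.alphabet != "aa":
                raise AlignmentError(f"record {r.id!r} is not amino-acid")

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __getitem__(self, seq_id: str) -> SeqRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def subset(self, ids: Sequence[str]) -> "ProteinAlignment":
        return ProteinAlignment(tuple(self[i] for i in ids))


@dataclass(frozen=True)
class CodonAlignment:
    """A gap-aware codon-delimited nucleotide alignment.

    Columns come in triplets; every gap run occupies whole codons and each
    ungapped row is a stop-free reading frame.
    """

    records: tuple[SeqRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentError("codon alignment needs at least 2 records")
        require_unique_ids(self.records)
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal aligned lengths: {sorted(lengths)}")
        n = lengths.pop()
        if n % 3:
            raise AlignmentError(f"alignment length {n} not divisible by 3")
        for r in self.records:
            if r.alphabet != "nt":
                raise AlignmentError(f"record {r.id!r} is not nucleotide")
            for c in range(0, n, 3):
                codon = r.residues[c: c + 3]
                if "-" in codon and codon != "---":
                    raise AlignmentError(
                        f"record {r.id!r}: partial gap in codon column {c // 3}"
                    )
            aa = translate_nt(r.ungapped)
            if "*" in aa:
                raise AlignmentError(
                    f"record {r.id!r}: internal stop at codon {aa.index('*')}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    @property
    def n_codons(self) -> int:
        return self.n_columns // 3

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __getitem__(self, seq_id: str) -> SeqRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def codons(self, seq_id: str) -> list[str]:
        s = self[seq_id].residues
        return [s[i: i + 3] for i in range(0, len(s), 3)]

    def window(self, start_nt: int, width_nt: int) -> "CodonAlignment":
        """Sub-alignment over columns [start_nt, start_nt + width_nt)."""
        if start_nt % 3 or width_nt % 3:
            raise AlignmentError("window boundaries must be codon-delimited")
        recs = tuple(
            SeqRecord(
                id=r.id,
                residues=r.residues[start_nt: start_nt + width_nt],
                alphabet="nt",
                description=r.description,
                aligned=True,
            )
            for r in self.records
        )
        return CodonAlignment(recs)

    def to_protein(self) -> ProteinAlignment:
        recs = tuple(
            SeqRecord(
                id=r.id,
                residues="".join(
                    "-" if r.residues[i: i + 3] == "---"
                    else CODON_TO_AA.get(r.residues[i: i + 3], "X")
                    for i in range(0, self.n_columns, 3)
                ),
                alphabet="aa",
                description=r.description,
                aligned=True,
            )
            for r in self.records
        )
        return ProteinAlignment(recs)


def read_protein_alignment(path: str | Path, fmt: str = "fasta") -> ProteinAlignment:
    """Read a protein multiple alignment (``fasta`` or ``clustal``)."""
    aln = AlignIO.read(str(path), fmt)
    recs = tuple(
        SeqRecord(id=r.id, residues=str(r.seq).upper(), alphabet="aa",
                  description=r.description, aligned=True)
        for r in aln
    )
    return ProteinAlignment(recs)


@dataclass(frozen=True)
class PairwiseStats:
    """EMBOSS-style statistics over alignment columns."""

    identity_pct: float
    similarity_pct: float
    gap_count: int
    gap_pct: float
    aligned_length: int

    def __post_init__(self) -> None:
        if not (0 <= self.identity_pct <= self.similarity_pct <= 100):
            raise ValueError("0 <= identity <= similarity <= 100 violated")


def _make_aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = mode
    if mode == "global":
        # end gaps are free, as in EMBOSS needle's default
        try:
            aligner.open_end_insertion_score = 0.0
            aligner.extend_end_insertion_score = 0.0
            aligner.open_end_deletion_score = 0.0
            aligner.extend_end_deletion_score = 0.0
        except AttributeError:  # Biopython < 1.88 attribute names
            aligner.target_end_open_gap_score = 0.0
            aligner.target_end_extend_gap_score = 0.0
            aligner.query_end_open_gap_score = 0.0
            aligner.query_end_extend_gap_score = 0.0
    return aligner


def stats_from_columns(row_a: str, row_b: str) -> PairwiseStats:
    """Compute identity/similarity/gap statistics from two aligned rows."""
    if len(row_a) != len(row_b):
        raise AlignmentError("aligned rows differ in length")
    n = len(row_a)
    ident = simil = gaps = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            gaps += 1
            continue
        if x == y:
            ident += 1
            simil += 1
            continue
        try:
            score = _BLOSUM62[x, y]
        except (KeyError, IndexError):
            score = -1
        if score > 0:
            simil += 1
    return PairwiseStats(
        identity_pct=100.0 * ident / n,
        similarity_pct=100.0 * simil / n,
        gap_count=gaps,
        gap_pct=100.0 * gaps / n,
        aligned_length=n,
    )


def align_pairwise(
    a: SeqRecord, b: SeqRecord, mode: str = "local"
) -> tuple[tuple[str, str], PairwiseStats, float]:
    """Optimal pairwise protein alignment and its EMBOSS-style statistics.

    Returns ``((aligned_a, aligned_b), stats, score)``.  Ties between
    optimal paths are broken deterministically (first path reported by the
    dynamic-programming traceback).
    """
    if mode not in ("local", "global"):
        raise ValueError("mode must be 'local' or 'global'")
    for r in (a, b):
        if r.alphabet != "aa":
            raise AlignmentError(f"record {r.id!r} is not amino-acid")
        if "-" in r.residues:
            raise AlignmentError(f"record {r.id!r} must be ungapped")
        if not r.residues:
            raise AlignmentError(f"record {r.id!r} is empty")
    aligner = _make_aligner(mode)
    result = aligner.align(a.residues, b.residues)
    best = result[0]
    row_a, row_b = str(best[0]), str(best[1])
    return (row_a, row_b), stats_from_columns(row_a, row_b), float(best.score)


def backtranslate_alignment(
    prot_aln: ProteinAlignment, cds: Iterable[SeqRecord] | Mapping[str, SeqRecord]
) -> CodonAlignment:
    """Expand a protein alignment to a codon-delimited nucleotide alignment.

    Each aa column becomes one codon column; ``-`` becomes ``---``.  Every
    CDS must translate (frame 0) exactly to its ungapped aligned protein.
    """
    if isinstance(cds, Mapping):
        cds_map = dict(cds)
    else:
        cds_map = {r.id: r for r in cds}
    rows: list[SeqRecord] = []
    for prot in prot_aln.records:
        nt = cds_map.get(prot.id)
        if nt is None:
            raise AlignmentError(f"no CDS supplied for aligned record {prot.id!r}")
        nt_seq = nt.ungapped
        aa_expected = prot.ungapped
        if len(nt_seq) < 3 * len(aa_expected):
            raise AlignmentError(
                f"record {prot.id!r}: CDS too short for {len(aa_expected)} residues"
            )
        aa_observed = translate_nt(nt_seq[: 3 * len(aa_expected)])
        for i, (e, o) in enumerate(zip(aa_expected, aa_observed)):
            if e != o and e != "X" and o != "X":
                raise AlignmentError(
                    f"record {prot.id!r}: CDS translation mismatch at aa position {i}"
                    f" (expected {e!r}, got {o!r})"
                )
        out: list[str] = []
        k = 0
        for ch in prot.residues:
            if ch == "-":
                out.append("---")
            else:
                out.append(nt_seq[3 * k: 3 * k + 3])
                k += 1
        rows.append(
            SeqRecord(id=prot.id, residues="".join(out), alphabet="nt",
                      description=prot.description, aligned=True)
        )
    return CodonAlignment(tuple(rows))
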