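"""In-silico degenerate-primer PCR and open-reading-frame screening.

Degenerate primers are IUPAC strings.  Matching is asymmetric, mirroring
wet-lab priming: a primer code matches any template base in its expansion,
while a template ``N`` matches any primer code.  Reverse primers are given
5'→3' on the antisense strand and matched against the reverse-complemented
template, i.e. their reverse complement is searched on the forward strand.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq

from .records import IUPAC_NT, SeqRecord, SequenceError, reverse_complement

logger = logging.getLogger(__name__)


class PrimerError(ValueError):
    """Raised for malformed primers."""


@dataclass(frozen=True)
class DegeneratePrimer:
    """An oligonucleotide with IUPAC ambiguity codes.

    ``direction`` is ``forward`` (sense strand) or ``reverse`` (given 5'→3'
    on the antisense strand, standard primer notation).
    """

    name: str
    iupac: str
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse"):
            raise PrimerError(f"primer {self.name!r}: direction must be forward/reverse")
        if len(self.iupac) < 10:
            raise PrimerError(f"primer {self.name!r}: length {len(self.iupac)} < 10")
        for pos, ch in enumerate(self.iupac.upper()):
            if ch not in IUPAC_NT:
                raise PrimerError(
                    f"primer {self.name!r}: invalid IUPAC code {ch!r} at position {pos}"
                )

    @property
    def degeneracy(self) -> int:
        n = 1
        for ch in self.iupac.upper():
            n *= len(IUPAC_NT[ch])
        return n


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on the forward strand of a template.

    ``start``/``end`` are 0-based half-open template coordinates of the
    full product including both primer sites.
    """

    template_id: str
    start: int
    end: int
    primer_pair: tuple[str, str]
    sequence: str
    fwd_mismatches: int = 0
    rev_mismatches: int = 0

    def __len__(self) -> int:
        return self.end - self.start

    def trimmed(self, fwd_len: int, rev_len: int) -> str:
        """Product with the primer-spanning ends removed."""
        return self.sequence[fwd_len: len(self.sequence) - rev_len]


def _base_matches(primer_code: str, template_base: str) -> bool:
    # asymmetric: template N matches anything; otherwise the template base
    # must be one of the primer code's expansions
    if template_base == "N":
        return True
    return template_base in IUPAC_NT[primer_code]


def primer_match_positions(
    primer_iupac: str, template: str, max_mismatches: int = 0
) -> list[tuple[int, int]]:
    """All (offset, n_mismatches) where the primer matches the template
    forward strand with at most ``max_mismatches`` IUPAC-aware mismatches."""
    primer = primer_iupac.upper()
    plen = len(primer)
    out: list[tuple[int, int]] = []
    for off in range(len(template) - plen + 1):
        mism = 0
        for i in range(plen):
            if not _base_matches(primer[i], template[off + i]):
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            out.append((off, mism))
    return out


def insilico_pcr(
    template: SeqRecord,
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    max_mismatches: int = 0,
    min_len: int = 0,
    max_len: int | None = None,
) -> list[Amplicon]:
    """Predict amplicons for a degenerate primer pair on one template.

    The forward primer is matched on the forward strand; the reverse primer
    (antisense 5'→3') is matched via its reverse complement on the forward
    strand, downstream of the forward site.  Amplicons are returned sorted
    by start coordinate, including both primer sites.
    """
    if template.alphabet != "nt":
        raise SequenceError(f"template {template.id!r} is not nucleotide")
    seq = template.ungapped.upper()
    rev_rc = reverse_complement(rev.iupac.upper())
    if len(fwd.iupac) > len(seq) or len(rev_rc) > len(seq):
        return []
    fwd_sites = primer_match_positions(fwd.iupac, seq, max_mismatches)
    rev_sites = primer_match_positions(rev_rc, seq, max_mismatches)
    amplicons: list[Amplicon] = []
    for fstart, fmis in fwd_sites:
        for rstart, rmis in rev_sites:
            end = rstart + len(rev_rc)
            if rstart < fstart + len(fwd.iupac):
                continue  # primer sites must not overlap
            length = end - fstart
            if length < min_len:
                continue
            if max_len is not None and length > max_len:
                continue
            amplicons.append(
                Amplicon(
                    template_id=template.id,
                    start=fstart,
                    end=end,
                    primer_pair=(fwd.name, rev.name),
                    sequence=seq[fstart:end],
                    fwd_mismatches=fmis,
                    rev_mismatches=rmis,
                )
            )
    amplicons.sort(key=lambda a: (a.start, a.end))
    return amplicons


@dataclass(frozen=True)
class OrfResult:
    status: str  # "intact" | "interrupted"
    aa: str
    reasons: list[int] = field(default_factory=list)  # codon indices of internal stops


def orf_screen(amplicon_seq: str, frame_offset: int = 0) -> OrfResult:
    """Translate from ``frame_offset`` to the last complete codon and flag
    internal stop codons.

    Trailing 1–2 nt are ignored.  Codons containing ambiguity codes
    translate to ``X``.  ``status`` is ``intact`` iff no internal stop.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    seq = amplicon_seq.upper().replace("-", "")
    if len(seq) < 3 + frame_offset:
        raise ValueError("sequence shorter than one codon in the requested frame")
    n_codons = (len(seq) - frame_offset) // 3
    coding = seq[frame_offset: frame_offset + 3 * n_codons]
    aa_chars: list[str] = []
    stops: list[int] = []
    for i in range(n_codons):
        codon = coding[3 * i: 3 * i + 3]
        if set(codon) <= set("ACGT"):
            aa = str(Seq(codon).translate())
        else:
            aa = "X"
        if aa == "*":
            stops.append(i)
        aa_chars.append(aa)
    status = "intact" if not stops else "interrupted"
    return OrfResult(status=status, aa="".join(aa_chars), reasons=stops)


def read_primer_tsv(path: str | Path) -> list[DegeneratePrimer]:
    """Read primers from a TSV with columns: name, direction, iupac.
    Lines starting with ``#`` are comments."""
    primers: list[DegeneratePrimer] = []
    with open(path) as fh:
        for row in csv.reader(
            (ln for ln in fh if ln.strip() and not ln.startswith("#")), delimiter="\t"
        ):
            if len(row) != 3:
                raise PrimerError(f"primer TSV row needs 3 columns, got {row!r}")
            name, direction, iupac = (c.strip() for c in row)
            primers.append(DegeneratePrimer(name=name, iupac=iupac, direction=direction))
    return primers


def write_amplicon_tsv(amplicons: Iterable[Amplicon], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "# template_id\tstart_1based\tend_1based\tlength\tfwd_primer\trev_primer"
            "\tfwd_mismatches\trev_mismatches\n"
        )
        for a in amplicons:
            fh.write(
                f"{a.template_id}\t{a.start + 1}\t{a.end}\t{len(a)}\t"
                f"{a.primer_pair[0]}\t{a.primer_pair[1]}\t{a.fwd_mismatches}\t{a.rev_mismatches}\n"
            )
    return path
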