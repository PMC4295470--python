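"""Kinase subdomain annotation, invariant-residue audit and RD/non-RD
classification.

The eukaryotic protein-kinase catalytic core is organised into eleven
conserved subdomains (I–XI) anchored by near-invariant motifs: the
glycine-rich loop (subdomain I, G-x-G-x-x-G), the VAIK lysine (II), the
alpha-C glutamate (III), the catalytic loop H-R-D...N (VIB), the DFG motif
opening the activation segment (VII) and the APE motif closing it (VIII).
Fragments are annotated by ordered anchor-motif matching rather than by
fixed offsets, because cloned fragments start and end at different
subdomains.

The RD/non-RD dichotomy keys on the residue immediately preceding the
catalytic aspartate of subdomain VIB: an arginine there marks an RD kinase;
its absence (frequently a cysteine in pattern-recognition receptors) marks
a non-RD kinase, a feature statistically associated with innate-immunity
receptors.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import align_pairwise, translate_nt
from .records import SeqRecord

logger = logging.getLogger(__name__)

SUBDOMAIN_ORDER = ["I", "II", "III", "IV", "V", "VIA", "VIB", "VII", "VIII", "IX", "X", "XI"]


class NotAKinaseError(ValueError):
    """Raised when too few anchor motifs are found for a kinase call."""


class AnchorOrderError(ValueError):
    """Raised when anchor motifs occur out of subdomain order."""


@dataclass(frozen=True)
class AnchorSpec:
    """One subdomain anchor: a regex plus the invariant residues it carries.

    ``invariants`` are (offset within the match, expected residue) pairs;
    the regex may tolerate substitutions there so the audit can flag them.
    ``strong`` anchors are specific enough to count toward the kinase call.
    """

    subdomain: str
    name: str
    pattern: str
    invariants: tuple[tuple[int, str], ...] = ()
    strong: bool = True


DEFAULT_ANCHORS: tuple[AnchorSpec, ...] = (
    AnchorSpec("I", "glycine-loop", r"G.G..G", ((0, "G"), (2, "G"), (5, "G"))),
    AnchorSpec("II", "VAIK-lysine", r"[VAIL]A[IVLM]K", ((3, "K"),)),
    AnchorSpec("III", "alphaC-glutamate", r"[LIVMFYW]E[LIVMFYW][LIVMFYW]",
               ((1, "E"),), strong=False),
    AnchorSpec("VIB", "catalytic-loop", r"H.[DN][LIVMFA]K..N",
               ((2, "D"), (4, "K"), (7, "N"))),
    AnchorSpec("VII", "DFG", r"D[FLWY][GAS][LIVMFY][ASTCG]", ((0, "D"), (2, "G"))),
    AnchorSpec("VIII", "APE", r"[ASG]PE", ((2, "E"),)),
)


@dataclass(frozen=True)
class AnchorMatch:
    subdomain: str
    name: str
    start: int  # 0-based position of the match in the fragment
    text: str


@dataclass(frozen=True)
class SubdomainMap:
    """Located anchors and the subdomain spans between them."""

    anchors: tuple[AnchorMatch, ...]  # in subdomain order
    seq_length: int

    @property
    def spans(self) -> dict[str, tuple[int, int]]:
        """Anchor-to-anchor spans, 0-based half-open; the last subdomain
        runs to the end of the fragment."""
        out: dict[str, tuple[int, int]] = {}
        for i, a in enumerate(self.anchors):
            end = self.anchors[i + 1].start if i + 1 < len(self.anchors) else self.seq_length
            out[a.subdomain] = (a.start, end)
        return out

    def anchor(self, subdomain: str) -> AnchorMatch | None:
        for a in self.anchors:
            if a.subdomain == subdomain:
                return a
        return None

    @property
    def first_subdomain(self) -> str:
        return self.anchors[0].subdomain

    @property
    def last_subdomain(self) -> str:
        return self.anchors[-1].subdomain

    @property
    def span_string(self) -> str:
        return f"{self.first_subdomain} → {self.last_subdomain}"


def annotate_subdomains(
    seq: SeqRecord,
    anchors: Sequence[AnchorSpec] = DEFAULT_ANCHORS,
    min_strong: int = 2,
) -> SubdomainMap:
    """Locate kinase subdomain anchors in an amino-acid fragment.

    Anchors are matched left to right in subdomain order (each searched
    after the previous match).  A fragment qualifies as a kinase iff at
    least ``min_strong`` strong anchors match in order; an anchor that
    occurs only *before* an earlier subdomain's match raises
    :class:`AnchorOrderError`.
    """
    if seq.alphabet != "aa":
        raise ValueError(f"record {seq.id!r} is not amino-acid")
    s = seq.ungapped
    matches: list[AnchorMatch] = []
    pos = 0
    for spec in anchors:
        m = re.search(spec.pattern, s[pos:])
        if m:
            start = pos + m.start()
            matches.append(AnchorMatch(spec.subdomain, spec.name, start, m.group(0)))
            pos = start + 1
        else:
            early = re.search(spec.pattern, s)
            if early is not None and matches and spec.strong:
                raise AnchorOrderError(
                    f"record {seq.id!r}: anchor {spec.name} ({spec.subdomain}) found at "
                    f"{early.start()} before {matches[-1].name} at {matches[-1].start}"
                )
    n_strong = sum(
        1 for m in matches
        if next(a for a in anchors if a.subdomain == m.subdomain).strong
    )
    if n_strong < min_strong:
        raise NotAKinaseError(
            f"record {seq.id!r}: not a kinase fragment "
            f"({n_strong} strong anchors matched, need {min_strong})"
        )
    return SubdomainMap(anchors=tuple(matches), seq_length=len(s))


@dataclass(frozen=True)
class InvariantCheck:
    expected: str
    observed: str  # residue, or "not spanned"
    subdomain: str
    position: int  # 0-based; -1 when not spanned

    @property
    def is_mismatch(self) -> bool:
        return self.observed != "not spanned" and self.observed != self.expected


@dataclass(frozen=True)
class KinaseAnnotation:
    """Full structural annotation of one kinase-domain fragment."""

    seq_id: str
    subdomains: SubdomainMap
    invariant_audit: tuple[InvariantCheck, ...]
    kinase_class: str  # "typical" | "atypical"
    catalytic_class: str  # "RD" | "nonRD" | "undetermined"
    rd_substituent: str | None
    activation_segment: tuple[int, int] | None  # [DFG start, APE end)

    def __post_init__(self) -> None:
        mismatches = [c for c in self.invariant_audit if c.is_mismatch]
        assert (self.kinase_class == "atypical") == bool(mismatches)
        assert (self.rd_substituent is not None) == (self.catalytic_class == "nonRD")


def audit_invariants(
    seq: SeqRecord,
    sd: SubdomainMap,
    anchors: Sequence[AnchorSpec] = DEFAULT_ANCHORS,
) -> tuple[tuple[InvariantCheck, ...], str]:
    """Check every configured invariant residue at its anchored position.

    Returns the audit list and the kinase class (``atypical`` iff at least
    one anchored invariant mismatches; anchors absent from the fragment are
    reported ``not spanned``, which is not a mismatch).
    """
    s = seq.ungapped
    checks: list[InvariantCheck] = []
    for spec in anchors:
        m = sd.anchor(spec.subdomain)
        for offset, expected in spec.invariants:
            if m is None:
                checks.append(InvariantCheck(expected, "not spanned", spec.subdomain, -1))
                continue
            pos = m.start + offset
            observed = s[pos] if pos < len(s) else "not spanned"
            checks.append(InvariantCheck(expected, observed, spec.subdomain, pos))
    mismatch = any(c.is_mismatch for c in checks)
    return tuple(checks), ("atypical" if mismatch else "typical")


def classify_rd(seq: SeqRecord, sd: SubdomainMap) -> tuple[str, str | None]:
    """RD / non-RD call from the residue preceding the catalytic aspartate.

    The catalytic Asp is the [DN] position of the subdomain-VIB
    catalytic-loop match (H-x-D, followed within the match by the invariant
    catalytic-loop lysine and asparagine).  Returns
    ``(catalytic_class, rd_substituent)``; ``undetermined`` when VIB is not
    spanned.
    """
    m = sd.anchor("VIB")
    if m is None:
        return "undetermined", None
    s = seq.ungapped
    preceding = s[m.start + 1]
    if preceding == "R":
        return "RD", None
    return "nonRD", preceding


def annotate(
    seq: SeqRecord,
    anchors: Sequence[AnchorSpec] = DEFAULT_ANCHORS,
    min_strong: int = 2,
) -> KinaseAnnotation:
    """One-call structural annotation: subdomains, invariants, RD class and
    activation segment."""
    sd = annotate_subdomains(seq, anchors, min_strong)
    audit, kclass = audit_invariants(seq, sd, anchors)
    cat, sub = classify_rd(seq, sd)
    dfg, ape = sd.anchor("VII"), sd.anchor("VIII")
    seg = (dfg.start, ape.start + len(ape.text)) if dfg and ape else None
    return KinaseAnnotation(
        seq_id=seq.id,
        subdomains=sd,
        invariant_audit=audit,
        kinase_class=kclass,
        catalytic_class=cat,
        rd_substituent=sub,
        activation_segment=seg,
    )


@dataclass(frozen=True)
class ConsensusMotif:
    """A functional consensus over the activation segment, anchored on the
    DFG match.

    ``positions`` are (offset from the DFG anchor start, allowed residues,
    weight) with weight ``key`` or ``recurring``.  The shipped defaults
    carry the residues named in the source analyses (the Pto activation
    segment's Ser/Thr pair and P+1-loop threonine, and their BRI1
    counterparts with Ser-1044 treated as an insertion); they are an
    editable, implementer-transcribed approximation of the full published
    consensus.
    """

    name: str
    positions: tuple[tuple[int, str, str], ...]
    anchor: str = "VII"  # anchored at the DFG match

    def __post_init__(self) -> None:
        offsets = [p[0] for p in self.positions]
        if offsets != sorted(set(offsets)):
            raise ValueError(f"motif {self.name!r}: offsets must be strictly increasing")
        if any(not p[1] for p in self.positions):
            raise ValueError(f"motif {self.name!r}: empty allowed-residue set")


# Pto numbering: DFG aspartate = residue 190, so Ser-198/Thr-199/Thr-204 sit
# at offsets 8/9/14 from the anchor.  BRI1 Ser-1042 and Thr-1045 map onto
# Pto Ser-198/Thr-199 once Ser-1044 is taken as an insertion.
PTO_MOTIF = ConsensusMotif(
    name="Pto_190_215",
    positions=((0, "D", "key"), (8, "ST", "key"), (9, "T", "key"), (14, "T", "key")),
)
BRI1_MOTIF = ConsensusMotif(
    name="BRI1_1039_1057",
    positions=((0, "D", "key"), (8, "S", "key"), (9, "ST", "key"), (14, "T", "recurring")),
)
# Alternative gap placement: BRI1 Ser-1042 treated as the insertion instead,
# aligning Ser-1044 with Pto Ser-198.
BRI1_MOTIF_ALT = ConsensusMotif(
    name="BRI1_1039_1057_ser1042_insertion",
    positions=((0, "D", "key"), (8, "S", "key"), (9, "ST", "key"), (14, "T", "recurring")),
)
DEFAULT_MOTIFS: tuple[ConsensusMotif, ...] = (PTO_MOTIF, BRI1_MOTIF)


def activation_segment_report(
    annotations: Iterable[KinaseAnnotation],
    seqs: Mapping[str, SeqRecord],
    motifs: Sequence[ConsensusMotif] = DEFAULT_MOTIFS,
) -> pd.DataFrame:
    """Match each sequence's activation segment against consensus motifs.

    One row per (sequence, motif): count of consensus positions matched, a
    match string with non-consensus positions rendered ``X``, and a
    ``not spanned`` flag when DFG/APE anchors are missing.
    """
    rows = []
    for ann in annotations:
        s = seqs[ann.seq_id].ungapped
        for motif in motifs:
            anchor = ann.subdomains.anchor(motif.anchor)
            if ann.activation_segment is None or anchor is None:
                rows.append({
                    "seq_id": ann.seq_id, "motif": motif.name, "spanned": False,
                    "n_matched": 0, "n_positions": len(motif.positions),
                    "match_string": "not spanned",
                })
                continue
            seg_start, seg_end = ann.activation_segment
            chars = []
            n_matched = 0
            for offset, allowed, _weight in motif.positions:
                pos = anchor.start + offset
                if pos >= len(s) or pos >= seg_end:
                    chars.append(".")
                    continue
                obs = s[pos]
                if obs in allowed:
                    n_matched += 1
                    chars.append(obs)
                else:
                    chars.append("X")
            rows.append({
                "seq_id": ann.seq_id, "motif": motif.name, "spanned": True,
                "n_matched": n_matched, "n_positions": len(motif.positions),
                "match_string": "".join(chars),
            })
    return pd.DataFrame(rows)


def _identity_range(seqs: list[str], alphabet: str) -> tuple[float, float] | None:
    """Min–max pairwise percent identity within a group (global alignment)."""
    if len(seqs) < 2:
        return None
    idents: list[float] = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if alphabet == "aa":
                a = SeqRecord(id=f"a{i}", residues=seqs[i], alphabet="aa")
                b = SeqRecord(id=f"b{j}", residues=seqs[j], alphabet="aa")
                _, stats, _ = align_pairwise(a, b, mode="global")
                idents.append(stats.identity_pct)
            else:
                # simple column identity for equal-length nt; fall back to
                # the shorter length as denominator otherwise
                n = min(len(seqs[i]), len(seqs[j]))
                same = sum(1 for x, y in zip(seqs[i], seqs[j]) if x == y)
                idents.append(100.0 * same / max(len(seqs[i]), len(seqs[j]), 1))
    return (min(idents), max(idents))


def summarize_families(
    annotations: Iterable[KinaseAnnotation],
    assignments: Mapping[str, str],
    seqs: Mapping[str, SeqRecord],
) -> pd.DataFrame:
    """Per-subfamily summary: member count, subdomain-span tally, nt length
    range, non-RD and atypical counts, and within-group aa/nt pairwise
    identity ranges.  Sequences without a group label are tallied under
    ``unassigned``."""
    by_group: dict[str, list[KinaseAnnotation]] = {}
    for ann in annotations:
        group = assignments.get(ann.seq_id, "unassigned")
        by_group.setdefault(group, []).append(ann)
    rows = []
    for group in sorted(by_group):
        anns = by_group[group]
        spans = Counter(a.subdomains.span_string for a in anns)
        nt_lengths = [len(seqs[a.seq_id].ungapped) for a in anns]
        nt_strs = [seqs[a.seq_id].ungapped for a in anns]
        aa_strs = [translate_nt(s) for s in nt_strs]
        aa_range = _identity_range(aa_strs, "aa")
        nt_range = _identity_range(nt_strs, "nt")
        rows.append({
            "group": group,
            "n": len(anns),
            "subdomain_spans": "; ".join(f"{k} ({v})" for k, v in sorted(spans.items())),
            "length_nt_min": min(nt_lengths),
            "length_nt_max": max(nt_lengths),
            "n_nonRD": sum(a.catalytic_class == "nonRD" for a in anns),
            "n_atypical": sum(a.kinase_class == "atypical" for a in anns),
            "aa_identity_min": round(aa_range[0], 1) if aa_range else float("nan"),
            "aa_identity_max": round(aa_range[1], 1) if aa_range else float("nan"),
            "nt_identity_min": round(nt_range[0], 1) if nt_range else float("nan"),
            "nt_identity_max": round(nt_range[1], 1) if nt_range else float("nan"),
        })
    return pd.DataFrame(rows)


def write_annotation_tsv(
    annotations: Iterable[KinaseAnnotation], path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# seq_id\tsubdomain_span\tkinase_class\tcatalytic_class\trd_substituent"
            "\tactivation_segment_1based\tinvariant_mismatches\n"
        )
        for a in annotations:
            seg = (
                f"{a.activation_segment[0] + 1}-{a.activation_segment[1]}"
                if a.activation_segment else "not spanned"
            )
            mism = ";".join(
                f"{c.subdomain}:{c.expected}{c.position + 1}{c.observed}"
                for c in a.invariant_audit if c.is_mismatch
            ) or "-"
            fh.write(
                f"{a.seq_id}\t{a.subdomains.span_string}\t{a.kinase_class}\t"
                f"{a.catalytic_class}\t{a.rd_substituent or '-'}\t{seg}\t{mism}\n"
            )
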