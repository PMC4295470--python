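"""Non-synonymous position maps and cross-group sharing summaries.

A codon column is non-synonymously variable within a group when at least
two distinct amino acids are encoded there among the group's gap-free
members.  Positions are classed ``exclusive`` (variable in one group),
``shared_2plus`` (two or more groups) or ``shared_all`` (every analysed
group); the classes form a nested chain.  A position enters the analysis
only if at least one group has the column gap-free in ≥ 2 members.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .align import CODON_TO_AA, CodonAlignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PositionRecord:
    """One aligned codon position of the variability map."""

    position: int  # 0-based codon column
    analysed: bool
    variable_groups: frozenset[str]
    shared_class: str | None  # exclusive | shared_2plus | shared_all | None
    residues: dict[str, Counter]  # group -> aa multiset over gap-free members


@dataclass(frozen=True)
class VariabilityTable:
    groups: tuple[str, ...]
    positions: tuple[PositionRecord, ...]

    @property
    def analysed_positions(self) -> list[PositionRecord]:
        return [p for p in self.positions if p.analysed]

    @property
    def variable_positions(self) -> list[PositionRecord]:
        return [p for p in self.positions if p.variable_groups]


def nonsyn_position_map(
    aln: CodonAlignment, groups: Mapping[str, Sequence[str]]
) -> VariabilityTable:
    """Map the codon positions subject to non-synonymous variation per
    group and their cross-group sharing.

    ``groups`` maps group label → member ids (each group needs ≥ 2
    members present in the alignment).  Columns where no group has ≥ 2
    gap-free members are skipped and logged.
    """
    for g, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        for m in members:
            aln[m]  # raises KeyError if absent
    group_labels = tuple(groups)
    codons = {m: aln.codons(m) for members in groups.values() for m in members}
    n_pos = aln.n_codons
    records: list[PositionRecord] = []
    n_skipped = 0
    for pos in range(n_pos):
        residues: dict[str, Counter] = {}
        variable: set[str] = set()
        any_group_ok = False
        for g, members in groups.items():
            aas = [
                CODON_TO_AA.get(codons[m][pos], "X")
                for m in members
                if codons[m][pos] != "---" and "-" not in codons[m][pos]
            ]
            residues[g] = Counter(aas)
            if len(aas) >= 2:
                any_group_ok = True
                if len(set(aas)) >= 2:
                    variable.add(g)
        if not any_group_ok:
            n_skipped += 1
            records.append(PositionRecord(pos, False, frozenset(), None, residues))
            continue
        if not variable:
            shared = None
        elif len(variable) == 1:
            shared = "exclusive"
        elif len(variable) == len(group_labels):
            shared = "shared_all"
        else:
            shared = "shared_2plus"
        records.append(PositionRecord(pos, True, frozenset(variable), shared, residues))
    if n_skipped:
        logger.info("%d positions skipped (no group with >= 2 gap-free members)", n_skipped)
    return VariabilityTable(groups=group_labels, positions=tuple(records))


def shared_position_summary(vt: VariabilityTable) -> dict:
    """Counts of analysed, variable, shared and exclusive positions.

    ``shared_all`` positions are also ``shared_2plus``.  Percentages of
    all-group sharing are reported against both candidate denominators
    (the variable positions and the 2-plus-shared positions).
    """
    if not vt.positions:
        raise ValueError("empty variability table")
    analysed = vt.analysed_positions
    variable = [p for p in analysed if p.variable_groups]
    shared2 = [p for p in variable if len(p.variable_groups) >= 2]
    shared_all = [p for p in variable if p.shared_class == "shared_all"]
    per_group_exclusive = {
        g: sum(1 for p in variable if p.variable_groups == frozenset([g]))
        for g in vt.groups
    }
    n_var = len(variable)
    n_s2 = len(shared2)
    return {
        "n_positions_analysed": len(analysed),
        "n_variable": n_var,
        "n_shared_2plus": n_s2,
        "n_shared_all": len(shared_all),
        "pct_shared_2plus_of_variable": 100.0 * n_s2 / n_var if n_var else 0.0,
        "pct_shared_all_of_variable": 100.0 * len(shared_all) / n_var if n_var else 0.0,
        "pct_shared_all_of_shared_2plus": 100.0 * len(shared_all) / n_s2 if n_s2 else 0.0,
        "per_group_exclusive": per_group_exclusive,
    }


def write_variability_tsv(vt: VariabilityTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# position_1based_aa\t"
            + "\t".join(f"variable_{g}" for g in vt.groups)
            + "\tshared_class\tresidues\n"
        )
        for p in vt.positions:
            if not p.analysed:
                continue
            flags = "\t".join(
                "1" if g in p.variable_groups else "0" for g in vt.groups
            )
            inventory = "; ".join(
                f"{g}:" + ",".join(f"{aa}:{n}" for aa, n in sorted(p.residues[g].items()))
                for g in vt.groups if p.residues[g]
            )
            fh.write(f"{p.position + 1}\t{flags}\t{p.shared_class or '-'}\t{inventory}\n")
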