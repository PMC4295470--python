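"""Synthetic codon-evolution generator for kinase-domain sequence families.

Families of homologous kinase-domain coding fragments are produced by
evolving an ancestral codon sequence along a simple guide tree (star
between groups, star or balanced within) under a continuous-time codon
process: stop-introducing changes are forbidden, transitions carry a kappa
weight, and non-synonymous changes carry a region-specific ω multiplier.
The default region map mirrors the empirical pattern the package is built
to detect — relaxed constraint (ω ≈ 1) over subdomains I–II, V–VIA and
VII–VIII, strong purifying selection (ω ≈ 0.1) elsewhere — and canonical
kinase anchor motifs (glycine loop, VAIK, catalytic loop with an RD or
non-RD Cys variant, DFG, APE) are planted at fixed codon offsets and
frozen against mutation so that structural classification has an exact
planted truth.

Branch lengths are in expected substitutions per codon site, calibrated at
the ancestral composition.  The substitution process is per-branch
Gillespie event sampling — simple and fully auditable — and every realized
substitution is recorded in a truth map with its position, codon change
and synonymous/non-synonymous label.  Same seed, same bytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .align import CODON_TO_AA, CodonAlignment, SENSE_CODONS, STOP_CODONS
from .pcr import DegeneratePrimer
from .records import IUPAC_NT, SeqRecord

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

# aa offset -> anchor residues of the canonical scaffold (165-codon default);
# the catalytic loop carries the RD arginine or its non-RD Cys substituent
ANCHOR_PLAN: dict[str, tuple[int, str]] = {
    "I": (10, "GEGSFG"),
    "II": (32, "VAVK"),
    "III": (50, "LEYL"),
    "VIB": (95, "HRDLKPSN"),
    "VII": (120, "DFGLA"),
    "VIII": (145, "APE"),
}
# background alphabet chosen so random filler cannot spell an anchor motif
_BACKGROUND_AA = "QTWMCHPS"


def canonical_kinase_protein(rd: bool = True, n_codons: int = 165, seed: int = 97) -> str:
    """A synthetic canonical kinase-domain fragment (aa) with every anchor
    motif at its planned offset.  Deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    chars = list(rng.choice(list(_BACKGROUND_AA), size=n_codons))
    for sub, (off, motif) in ANCHOR_PLAN.items():
        motif_seq = motif if (rd or sub != "VIB") else "HCDLKPSN"
        if off + len(motif_seq) > n_codons:
            raise ValueError(f"anchor {sub} does not fit in {n_codons} codons")
        chars[off: off + len(motif_seq)] = list(motif_seq)
    return "".join(chars)


@lru_cache(maxsize=None)
def _codons_for_aa(aa: str) -> tuple[str, ...]:
    return tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa)


@lru_cache(maxsize=None)
def _neighbors(codon: str) -> tuple[tuple[str, bool, bool], ...]:
    """(target, is_synonymous, is_transition) for each non-stop single-nt
    neighbour of a sense codon."""
    out = []
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            out.append(
                (mutant, CODON_TO_AA[mutant] == CODON_TO_AA[codon],
                 (codon[pos], alt) in _TRANSITIONS)
            )
    return tuple(out)


@dataclass(frozen=True)
class SubstitutionEvent:
    """One realized substitution of the truth map."""

    lineage: str
    codon_pos: int
    from_codon: str
    to_codon: str
    synonymous: bool


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated family.

    Defaults mimic the empirical scale of the cloned families: 4 groups of
    8 members, 165 codons (495 nt), kappa 2, relaxed ω = 1 over the
    subdomain I–II, V–VIA and VII–VIII analogue regions and ω = 0.1
    elsewhere, with moderate between-group and shallow within-group
    divergence.
    """

    n_groups: int = 4
    members_per_group: int = 8
    n_codons: int = 165
    kappa: float = 2.0
    between_group_branch: float = 0.35
    within_group_branch: float = 0.12
    tree_shape: str = "star"  # star | balanced (within groups)
    regions: tuple[tuple[int, int, float], ...] | None = None  # (start, end, omega)
    relaxed_omega: float = 1.0
    constrained_omega: float = 0.1
    plant_anchors: bool = True
    rd_groups: tuple[bool, ...] | None = None  # default: alternating RD/non-RD
    planted_shared_nonsyn: tuple[int, ...] = ()
    pseudogene_fraction: float = 0.0
    seed: int = 0

    def resolved_regions(self) -> tuple[tuple[int, int, float], ...]:
        if self.regions is not None:
            regs = tuple(self.regions)
        else:
            regs = default_regions(
                self.n_codons, self.relaxed_omega, self.constrained_omega
            )
        # regions must tile [0, n_codons) without overlap
        pos = 0
        for start, end, omega in regs:
            if start != pos or end <= start or omega < 0:
                raise ValueError(f"region map does not tile the sequence: {regs}")
            pos = end
        if pos != self.n_codons:
            raise ValueError("region map does not cover the full sequence")
        return regs

    def rd_flags(self) -> tuple[bool, ...]:
        if self.rd_groups is not None:
            if len(self.rd_groups) != self.n_groups:
                raise ValueError("rd_groups length must equal n_groups")
            return self.rd_groups
        return tuple(g % 2 == 0 for g in range(self.n_groups))


def default_regions(
    n_codons: int, relaxed: float = 1.0, constrained: float = 0.1
) -> tuple[tuple[int, int, float], ...]:
    """Relaxed-ω regions over the subdomain I–II, V–VIA and VII–VIII
    analogues of the 165-codon scaffold, scaled to ``n_codons``."""
    anchors = {k: v[0] for k, v in ANCHOR_PLAN.items()}
    scale = n_codons / 165.0
    bounds = [
        (int(anchors["I"] * scale), int(anchors["III"] * scale)),        # I–II
        (int(70 * scale), int(anchors["VIB"] * scale)),                  # V–VIA
        (int(anchors["VII"] * scale), int((anchors["VIII"] + 3) * scale)),  # VII–VIII
    ]
    regions: list[tuple[int, int, float]] = []
    pos = 0
    for start, end in bounds:
        if start > pos:
            regions.append((pos, start, constrained))
        regions.append((start, end, relaxed))
        pos = end
    if pos < n_codons:
        regions.append((pos, n_codons, constrained))
    return tuple(regions)


def _omega_array(regions: Sequence[tuple[int, int, float]], n_codons: int) -> np.ndarray:
    omega = np.empty(n_codons)
    for start, end, w in regions:
        omega[start:end] = w
    return omega


def _site_rate(codon: str, omega: float, kappa: float) -> float:
    rate = 0.0
    for _target, syn, ts in _neighbors(codon):
        w = kappa if ts else 1.0
        if not syn:
            w *= omega
        rate += w
    return rate


def _evolve_branch(
    codons: list[str],
    t: float,
    omega: np.ndarray,
    kappa: float,
    masked: np.ndarray,
    z_norm: float,
    rng: np.random.Generator,
    lineage: str,
    events: list[SubstitutionEvent],
) -> list[str]:
    """Gillespie event sampling along one branch of length ``t`` (expected
    substitutions per unmasked codon site, normalized by ``z_norm``)."""
    codons = list(codons)
    rates = np.array([
        0.0 if masked[i] else _site_rate(c, omega[i], kappa)
        for i, c in enumerate(codons)
    ])
    elapsed = 0.0
    while True:
        total = rates.sum()
        if total <= 0:
            break
        elapsed += rng.exponential(z_norm / total)
        if elapsed > t:
            break
        site = rng.choice(len(codons), p=rates / total)
        neigh = _neighbors(codons[site])
        weights = np.array([
            (kappa if ts else 1.0) * (1.0 if syn else omega[site])
            for _tg, syn, ts in neigh
        ])
        pick = rng.choice(len(neigh), p=weights / weights.sum())
        target, syn, _ts = neigh[pick]
        events.append(
            SubstitutionEvent(lineage, int(site), codons[site], target, bool(syn))
        )
        codons[site] = target
        rates[site] = _site_rate(target, omega[site], kappa)
    return codons


def calibrate_branch_for_ks(
    codons: Sequence[str], target_ks: float, omega: float, kappa: float = 2.0
) -> float:
    """Branch length (expected substitutions per codon site) at which the
    expected synonymous divergence of ``codons`` is ``target_ks``.

    Derived at the ancestral composition: with mean total site rate Z and
    mean synonymous site rate z_s, a branch of length t yields t·z_s/Z
    synonymous events per codon, spread over the mean NG86 synonymous site
    count S̄."""
    from .selection import codon_sites

    s_sites = sum(codon_sites(c)[0] for c in codons)
    z_tot = z_syn = 0.0
    for c in codons:
        for _tg, syn, ts in _neighbors(c):
            w = kappa if ts else 1.0
            if syn:
                z_syn += w
                z_tot += w
            else:
                z_tot += w * omega
    n = len(codons)
    z_tot /= n
    z_syn /= n
    s_bar = s_sites / n
    if z_syn <= 0:
        raise ValueError("no synonymous changes possible; cannot calibrate")
    return target_ks * s_bar * z_tot / z_syn


@dataclass
class SimResult:
    """Everything a validation run needs: the alignment, the group map and
    the planted truth."""

    alignment: CodonAlignment
    groups: dict[str, list[str]]
    events: list[SubstitutionEvent]
    rd_labels: dict[str, str]  # group -> "RD" | "nonRD"
    anchor_codon_offsets: dict[str, int]  # subdomain -> codon offset (planted)
    planted_shared_nonsyn: tuple[int, ...]
    pseudogenes: dict[str, str]  # member id -> frameshift-degraded nt
    ancestor: tuple[str, ...]
    config: SimConfig


def _ancestral_codons(cfg: SimConfig, rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
    """Uniform sense-codon ancestor with anchor codons forced and masked."""
    codons = list(rng.choice(SENSE_CODONS, size=cfg.n_codons))
    masked = np.zeros(cfg.n_codons, dtype=bool)
    if cfg.plant_anchors:
        for sub, (off, motif) in ANCHOR_PLAN.items():
            if cfg.n_codons < off + len(motif):
                raise ValueError(f"anchor {sub} outside sequence of {cfg.n_codons} codons")
            for k, aa in enumerate(motif):
                codons[off + k] = rng.choice(_codons_for_aa(aa))
                masked[off + k] = True
    return codons, masked


def simulate_family(cfg: SimConfig) -> SimResult:
    """Simulate one family of kinase-domain coding fragments.

    The alignment is the true homology (gapless); anchor codons are frozen;
    the VIB catalytic loop of each group's ancestor carries Arg (RD) or Cys
    (non-RD) according to the group's flag; every substitution event is
    recorded.  Reproducible byte-for-byte given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    regions = cfg.resolved_regions()
    omega = _omega_array(regions, cfg.n_codons)
    rd_flags = cfg.rd_flags()
    ancestor, masked = _ancestral_codons(cfg, rng)
    # normalization: mean site rate of the unmasked ancestor
    unmasked_rates = [
        _site_rate(c, omega[i], cfg.kappa)
        for i, c in enumerate(ancestor) if not masked[i]
    ]
    z_norm = float(np.mean(unmasked_rates)) if unmasked_rates else 1.0
    events: list[SubstitutionEvent] = []
    groups: dict[str, list[str]] = {}
    rd_labels: dict[str, str] = {}
    rows: list[SeqRecord] = []
    rd_pos = ANCHOR_PLAN["VIB"][0] + 1 if cfg.plant_anchors else None
    for g in range(cfg.n_groups):
        label = f"group{g + 1}"
        rd = rd_flags[g]
        rd_labels[label] = "RD" if rd else "nonRD"
        g_anc = _evolve_branch(
            ancestor, cfg.between_group_branch, omega, cfg.kappa, masked,
            z_norm, rng, f"{label}.ancestor", events,
        )
        if rd_pos is not None:
            g_anc[rd_pos] = rng.choice(_codons_for_aa("R" if rd else "C"))
        member_ids = [f"{label}.m{m + 1}" for m in range(cfg.members_per_group)]
        groups[label] = member_ids
        if cfg.tree_shape == "balanced" and cfg.members_per_group >= 4:
            # two-level shape: half the within-group branch to a subclade
            # ancestor shared by half the members, half to each member
            half = cfg.members_per_group // 2
            subclades = [member_ids[:half], member_ids[half:]]
            for sub_ids in subclades:
                sub_anc = _evolve_branch(
                    g_anc, cfg.within_group_branch / 2, omega, cfg.kappa, masked,
                    z_norm, rng, f"{label}.sub", events,
                )
                for mid in sub_ids:
                    member = _evolve_branch(
                        sub_anc, cfg.within_group_branch / 2, omega, cfg.kappa,
                        masked, z_norm, rng, mid, events,
                    )
                    rows.append(SeqRecord(id=mid, residues="".join(member),
                                          alphabet="nt", aligned=True))
        else:
            for mid in member_ids:
                member = _evolve_branch(
                    g_anc, cfg.within_group_branch, omega, cfg.kappa, masked,
                    z_norm, rng, mid, events,
                )
                rows.append(SeqRecord(id=mid, residues="".join(member),
                                      alphabet="nt", aligned=True))
    # deterministic planting of shared non-synonymous positions: in every
    # group, half the members receive an alternative amino acid
    for pos in cfg.planted_shared_nonsyn:
        if not (0 <= pos < cfg.n_codons) or masked[pos]:
            raise ValueError(f"planted non-syn position {pos} invalid (masked or out of range)")
    row_index = {r.id: i for i, r in enumerate(rows)}
    for pos in cfg.planted_shared_nonsyn:
        for label, member_ids in groups.items():
            base = rows[row_index[member_ids[0]]].residues[3 * pos: 3 * pos + 3]
            base_aa = CODON_TO_AA[base]
            alt_aa = "W" if base_aa != "W" else "C"
            alt_codon = _codons_for_aa(alt_aa)[0]
            keep_codon = _codons_for_aa(base_aa)[0]
            for k, mid in enumerate(member_ids):
                i = row_index[mid]
                chosen = alt_codon if k < len(member_ids) // 2 else keep_codon
                s = rows[i].residues
                rows[i] = replace(rows[i], residues=s[:3 * pos] + chosen + s[3 * pos + 3:])
    # optional frameshift-degraded copies (kept out of the codon alignment)
    pseudogenes: dict[str, str] = {}
    if cfg.pseudogene_fraction > 0:
        all_ids = [r.id for r in rows]
        n_ps = max(1, int(round(cfg.pseudogene_fraction * len(all_ids))))
        for mid in rng.choice(all_ids, size=n_ps, replace=False):
            seq = rows[row_index[mid]].residues
            pseudogenes[f"{mid}.psi"] = degrade_to_pseudogene(
                seq, n_indels=1, seed=int(rng.integers(0, 2**31 - 1))
            )
    alignment = CodonAlignment(tuple(rows))
    anchor_offsets = (
        {sub: off for sub, (off, _m) in ANCHOR_PLAN.items()} if cfg.plant_anchors else {}
    )
    return SimResult(
        alignment=alignment,
        groups=groups,
        events=events,
        rd_labels=rd_labels,
        anchor_codon_offsets=anchor_offsets,
        planted_shared_nonsyn=cfg.planted_shared_nonsyn,
        pseudogenes=pseudogenes,
        ancestor=tuple(ancestor),
        config=cfg,
    )


def simulate_pair(
    n_codons: int,
    omega: float,
    kappa: float = 2.0,
    target_ks: float = 0.3,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Two codon sequences diverged from a common ancestor at a calibrated
    synonymous divergence (expected Ks ≈ ``target_ks``), uniform ω."""
    rng = np.random.default_rng(seed)
    ancestor = list(rng.choice(SENSE_CODONS, size=n_codons))
    om = np.full(n_codons, float(omega))
    masked = np.zeros(n_codons, dtype=bool)
    z = float(np.mean([_site_rate(c, omega, kappa) for c in ancestor]))
    t_total = calibrate_branch_for_ks(ancestor, target_ks, omega, kappa)
    events: list[SubstitutionEvent] = []
    a = _evolve_branch(ancestor, t_total / 2, om, kappa, masked, z, rng, "a", events)
    b = _evolve_branch(ancestor, t_total / 2, om, kappa, masked, z, rng, "b", events)
    return a, b


def degrade_to_pseudogene(
    seq: str,
    n_indels: int = 1,
    seed: int = 0,
    protected: Sequence[tuple[int, int]] = (),
) -> str:
    """Introduce 1–2 nt insertions/deletions at random unprotected
    positions, emulating a frameshift-degraded pseudogene copy."""
    if n_indels < 1:
        raise ValueError("n_indels must be >= 1")
    if len(seq) < 30:
        raise ValueError("sequence shorter than 10 codons")
    rng = np.random.default_rng(seed)
    s = list(seq)
    for _ in range(n_indels):
        while True:
            pos = int(rng.integers(3, len(s) - 3))
            if not any(a <= pos < b for a, b in protected):
                break
        size = int(rng.integers(1, 3))
        if rng.random() < 0.5:
            del s[pos: pos + size]
        else:
            ins = "".join(rng.choice(list(_BASES), size=size))
            s[pos:pos] = list(ins)
    return "".join(s)


def plant_primer_sites(
    seq: str,
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    positions: tuple[int, int],
    seed: int = 0,
    protected: Sequence[tuple[int, int]] = (),
) -> str:
    """Write one concrete expansion of each degenerate primer into a
    template at the stated coordinates.

    The forward site is written as-is at ``positions[0]``; the reverse site
    is written as the reverse complement of an expansion of the reverse
    primer (which is given 5'→3' on the antisense strand) ending the
    amplicon at ``positions[1] + len(rev)``.  In-silico PCR with the same
    primers then recovers the amplicon.
    """
    from .records import reverse_complement

    rng = np.random.default_rng(seed)

    def expand(iupac: str) -> str:
        return "".join(rng.choice(sorted(IUPAC_NT[ch])) for ch in iupac.upper())

    fpos, rpos = positions
    fsite = expand(fwd.iupac)
    rsite = reverse_complement(expand(rev.iupac))
    for start, length in ((fpos, len(fsite)), (rpos, len(rsite))):
        if start < 0 or start + length > len(seq):
            raise ValueError(f"primer site at {start} out of range")
        for a, b in protected:
            if start < b and a < start + length:
                raise ValueError(f"primer site at {start} overlaps protected span ({a},{b})")
    if fpos + len(fsite) > rpos:
        raise ValueError("primer sites overlap each other")
    s = list(seq)
    s[fpos: fpos + len(fsite)] = list(fsite)
    s[rpos: rpos + len(rsite)] = list(rsite)
    return "".join(s)
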