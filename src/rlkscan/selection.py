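"""Pairwise Ka/Ks estimation and sliding-window selection scans.

The default estimator is the Nei–Gojobori (1986) codon-counting method:
synonymous site counts per codon are the synonymous fraction of its nine
single-nucleotide neighbours (changes to stop codons count as
non-synonymous), difference counts average the synonymous/non-synonymous
step assignment over all minimal mutational pathways between differing
codons (pathways through stop codons are discarded), and the Jukes–Cantor
correction d = −(3/4)·ln(1 − (4/3)p) maps proportions to rates.  ω = Ka/Ks
≪ 1 indicates purifying selection, ω ≈ 1 relaxed constraint, ω > 1
positive selection.

``YN-approx`` applies transition/transversion weighting with a kappa
estimated from four-fold degenerate sites — a documented approximation of
the Yang–Nielsen (yn00) model — on the same pathway machinery.

Window scans use a 75 bp window sliding in 15 bp steps over the
codon-delimited alignment; per-window group means and standard errors are
compared between groups with the two-sided rank-sum (Wilcoxon) test
combined with a fold-change criterion, and each window's ω distribution
can be tested against 1 with a one-sided signed-rank test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .align import CODON_TO_AA, CodonAlignment, STOP_CODONS

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class KaKsError(ValueError):
    """Raised when an estimate cannot be formed (no comparable codons)."""


def _is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITIONS


@lru_cache(maxsize=None)
def codon_sites(codon: str, kappa: float = 1.0) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts of one sense codon.

    Each position contributes one site, split by the (kappa-weighted)
    fraction of its three single-nucleotide changes that are synonymous;
    changes to stop codons are non-synonymous.  ``kappa=1`` gives plain
    NG86 counts with S + N = 3 exactly.
    """
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        w_syn = w_tot = 0.0
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            w = kappa if _is_transition(codon[pos], alt) else 1.0
            w_tot += w
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == aa:
                w_syn += w
        syn += w_syn / w_tot
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_path_differences(
    a: str, b: str, kappa: float = 1.0
) -> tuple[float, float] | None:
    """(synonymous, non-synonymous) difference counts between two sense
    codons, averaged over all minimal mutational pathways.

    Pathways passing through stop codons are discarded; with kappa ≠ 1
    pathways are weighted by the product of their step weights (kappa per
    transition step).  Returns ``None`` if every pathway hits a stop.
    """
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return (0.0, 0.0)
    total_w = 0.0
    syn_acc = nonsyn_acc = 0.0
    for order in itertools.permutations(diff_pos):
        current = a
        syn = nonsyn = 0.0
        weight = 1.0
        ok = True
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _is_transition(current[pos], nxt[pos]):
                weight *= kappa
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if ok:
            total_w += weight
            syn_acc += weight * syn
            nonsyn_acc += weight * nonsyn
    if total_w == 0.0:
        return None
    return (syn_acc / total_w, nonsyn_acc / total_w)


def jukes_cantor(p: float) -> float:
    """JC correction d = −(3/4)·ln(1 − (4/3)p); undefined for p ≥ 3/4."""
    if p >= 0.75:
        raise ValueError(f"proportion {p:.3f} >= 3/4: correction undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsEstimate:
    """A pairwise Ka/Ks estimate with its site and difference counts.

    ``omega`` is ``inf`` when Ks = 0 < Ka and ``nan`` when Ka = Ks = 0;
    ``saturated`` marks pn or ps beyond the Jukes–Cantor domain.
    """

    pair: tuple[str, str]
    N: float
    S: float
    Nd: float
    Sd: float
    pn: float
    ps: float
    Ka: float
    Ks: float
    omega: float
    method: str
    n_codons_compared: int
    n_codons_skipped: int
    saturated: bool = False
    kappa: float = 1.0

    @property
    def defined(self) -> bool:
        return math.isfinite(self.omega) and not self.saturated


def _comparable_codon_pairs(
    codons_a: Sequence[str], codons_b: Sequence[str]
) -> tuple[list[tuple[str, str]], int]:
    pairs: list[tuple[str, str]] = []
    skipped = 0
    unambiguous = set("ACGT")
    for ca, cb in zip(codons_a, codons_b):
        if "-" in ca or "-" in cb or not (set(ca) <= unambiguous and set(cb) <= unambiguous):
            skipped += 1
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            skipped += 1
            continue
        pairs.append((ca, cb))
    return pairs, skipped


def estimate_kappa(codon_pairs: Iterable[tuple[str, str]]) -> float:
    """Transition/transversion rate ratio from four-fold degenerate sites.

    Third positions of codons whose first two bases match and are four-fold
    degenerate are compared under the Kimura two-parameter model
    (kappa = 2A/B − 1).  Falls back to 2.0 when fewer than 10 such sites or
    when the K80 estimate is undefined; the result is clipped to [0.1, 20].
    """
    n = ts = tv = 0
    for ca, cb in codon_pairs:
        if ca[:2] != cb[:2]:
            continue
        prefix = ca[:2]
        family = {prefix + b for b in _BASES}
        if family & STOP_CODONS:
            continue
        if len({CODON_TO_AA[c] for c in family}) != 1:
            continue
        n += 1
        if ca[2] != cb[2]:
            if _is_transition(ca[2], cb[2]):
                ts += 1
            else:
                tv += 1
    if n < 10:
        return 2.0
    P, Q = ts / n, tv / n
    try:
        A = -0.5 * math.log(1 - 2 * P - Q)
        B = -0.5 * math.log(1 - 2 * Q)
    except ValueError:
        return 2.0
    if B <= 0:
        return 20.0
    return float(np.clip(2 * A / B - 1, 0.1, 20.0))


def kaks_pair(
    codons_a: Sequence[str],
    codons_b: Sequence[str],
    ids: tuple[str, str] = ("a", "b"),
    method: str = "NG86",
) -> KaKsEstimate:
    """Pairwise Ka, Ks and ω from two codon-delimited rows.

    Codon columns with a gap or ambiguity in either row are skipped (count
    recorded), as are codon pairs whose every minimal pathway crosses a
    stop codon.  Symmetric in its arguments.
    """
    if method not in ("NG86", "YN-approx"):
        raise ValueError("method must be 'NG86' or 'YN-approx'")
    if len(codons_a) != len(codons_b):
        raise KaKsError("rows differ in codon count")
    pairs, skipped = _comparable_codon_pairs(codons_a, codons_b)
    kappa = estimate_kappa(pairs) if method == "YN-approx" else 1.0
    N = S = Nd = Sd = 0.0
    n_used = 0
    for ca, cb in pairs:
        diffs = codon_path_differences(ca, cb, kappa)
        if diffs is None:
            skipped += 1
            logger.debug("codon pair %s/%s skipped: all pathways hit stops", ca, cb)
            continue
        sa, na = codon_sites(ca, kappa)
        sb, nb = codon_sites(cb, kappa)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = diffs
        Sd += sd
        Nd += nd
        n_used += 1
    if n_used == 0:
        raise KaKsError(f"pair {ids}: zero comparable codons")
    pn = Nd / N if N else 0.0
    ps = Sd / S if S else 0.0
    saturated = pn >= 0.75 or ps >= 0.75
    if saturated:
        ka = ks = float("nan")
        omega = float("nan")
    else:
        ka = jukes_cantor(pn)
        ks = jukes_cantor(ps)
        if ks > 0:
            omega = ka / ks
        elif ka > 0:
            omega = float("inf")
        else:
            omega = float("nan")
    return KaKsEstimate(
        pair=ids, N=N, S=S, Nd=Nd, Sd=Sd, pn=pn, ps=ps, Ka=ka, Ks=ks,
        omega=omega, method=method, n_codons_compared=n_used,
        n_codons_skipped=skipped, saturated=saturated, kappa=kappa,
    )


def kaks_alignment_pair(
    aln: CodonAlignment, id_a: str, id_b: str, method: str = "NG86"
) -> KaKsEstimate:
    return kaks_pair(aln.codons(id_a), aln.codons(id_b), ids=(id_a, id_b), method=method)


@dataclass(frozen=True)
class WindowProfile:
    """Per-window ω summary for one group of sequences."""

    group: str
    window_index: int
    start_nt: int  # 0-based alignment coordinate, multiple of step
    omegas: tuple[float, ...]  # defined omegas only
    mean: float
    sem: float
    n_pairs_used: int
    n_excluded: int


def n_windows(length_nt: int, window_nt: int = 75, step_nt: int = 15) -> int:
    if length_nt < window_nt:
        return 0
    return (length_nt - window_nt) // step_nt + 1


def window_profile(
    aln: CodonAlignment,
    group: Sequence[str],
    group_label: str = "group",
    window_nt: int = 75,
    step_nt: int = 15,
    method: str = "NG86",
    min_codons: int = 10,
) -> list[WindowProfile]:
    """Sliding-window ω profile for all unordered pairs within a group.

    Windows start at 0, step, 2·step … while start + window ≤ alignment
    length (alignment coordinates: gap columns count toward the window).
    Undefined or saturated ω values, and pairs with fewer than
    ``min_codons`` comparable codons in a window, are excluded from the
    mean and SEM with the exclusion count recorded.
    """
    if window_nt % 3 or step_nt % 3:
        raise ValueError("window and step must be divisible by 3")
    if aln.n_columns < window_nt:
        raise ValueError(
            f"alignment length {aln.n_columns} shorter than one window ({window_nt})"
        )
    ids = list(group)
    if len(ids) < 2:
        raise ValueError(f"group {group_label!r} needs at least 2 members")
    rows = {i: aln.codons(i) for i in ids}
    profiles: list[WindowProfile] = []
    n_win = n_windows(aln.n_columns, window_nt, step_nt)
    for w in range(n_win):
        start = w * step_nt
        c0, c1 = start // 3, (start + window_nt) // 3
        omegas: list[float] = []
        excluded = 0
        for a, b in itertools.combinations(ids, 2):
            try:
                est = kaks_pair(rows[a][c0:c1], rows[b][c0:c1], ids=(a, b), method=method)
            except KaKsError:
                excluded += 1
                continue
            if est.n_codons_compared < min_codons or not est.defined:
                excluded += 1
                continue
            omegas.append(est.omega)
        arr = np.asarray(omegas)
        mean = float(arr.mean()) if len(arr) else float("nan")
        sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else float("nan")
        profiles.append(
            WindowProfile(
                group=group_label, window_index=w, start_nt=start,
                omegas=tuple(omegas), mean=mean, sem=sem,
                n_pairs_used=len(omegas), n_excluded=excluded,
            )
        )
    return profiles


@dataclass(frozen=True)
class WindowComparison:
    """A rank-sum comparison of two ω samples (between groups at one
    window, or between two windows of one group)."""

    window_index: int
    label_1: str
    label_2: str
    statistic: float
    p_value: float
    fold_change: float
    flag_significant: bool


def _ranksum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided rank-sum p: exact enumeration when both n ≤ 10, otherwise
    the tie-corrected normal approximation."""
    x, y = np.asarray(x), np.asarray(y)
    if np.array_equal(np.sort(x), np.sort(y)):
        return 0.0, 1.0
    method = "exact" if (len(x) <= 10 and len(y) <= 10) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_window_groups(
    p1: Sequence[WindowProfile],
    p2: Sequence[WindowProfile],
    alpha: float = 1e-4,
    fold_min: float = 2.0,
) -> list[WindowComparison]:
    """Window-by-window rank-sum comparison of two groups' ω samples.

    Profiles must share window geometry.  A window is flagged significant
    iff p < alpha and the fold change (mean₁/mean₂) exceeds ``fold_min``.
    Windows where either side has fewer than 2 defined ω are skipped and
    logged.
    """
    if [p.start_nt for p in p1] != [p.start_nt for p in p2]:
        raise ValueError("window geometries differ between profile sets")
    out: list[WindowComparison] = []
    for a, b in zip(p1, p2):
        if len(a.omegas) < 2 or len(b.omegas) < 2:
            logger.info(
                "window %d skipped: %d vs %d defined omegas",
                a.window_index, len(a.omegas), len(b.omegas),
            )
            continue
        statistic, p = _ranksum(a.omegas, b.omegas)
        fold = a.mean / b.mean if b.mean > 0 else float("inf")
        out.append(
            WindowComparison(
                window_index=a.window_index, label_1=a.group, label_2=b.group,
                statistic=statistic, p_value=p, fold_change=fold,
                flag_significant=(p < alpha and fold > fold_min),
            )
        )
    return out


def compare_two_windows(
    profiles: Sequence[WindowProfile],
    window_hi: int,
    window_lo: int,
    alpha: float = 1e-4,
    fold_min: float = 2.0,
) -> WindowComparison:
    """Within-group comparison of one window's ω sample against another
    (the fold-change-versus-lowest-window style of contrast)."""
    by_idx = {p.window_index: p for p in profiles}
    a, b = by_idx[window_hi], by_idx[window_lo]
    if len(a.omegas) < 2 or len(b.omegas) < 2:
        raise ValueError("both windows need >= 2 defined omegas")
    statistic, p = _ranksum(a.omegas, b.omegas)
    fold = a.mean / b.mean if b.mean > 0 else float("inf")
    return WindowComparison(
        window_index=window_hi,
        label_1=f"{a.group}:w{window_hi}",
        label_2=f"{b.group}:w{window_lo}",
        statistic=statistic, p_value=p, fold_change=fold,
        flag_significant=(p < alpha and fold > fold_min),
    )


def exact_signed_rank_greater(diffs: Sequence[float]) -> float:
    """One-sided exact signed-rank p (H1: median > 0) by enumerating all
    2^n sign assignments with mid-ranks; zero differences are dropped."""
    d = np.asarray([x for x in diffs if x != 0.0])
    n = len(d)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    count = 0
    total = 1 << n
    for mask in range(total):
        w = 0.0
        for i in range(n):
            if mask >> i & 1:
                w += ranks[i]
        if w >= w_obs - 1e-12:
            count += 1
    return count / total


def test_window_vs_one(
    profile: WindowProfile, alpha: float = 0.05
) -> tuple[float, bool]:
    """One-sided signed-rank test of a window's ω sample against 1.

    Exact mid-rank enumeration for n ≤ 12, normal approximation beyond.
    All ω exactly 1 is degenerate and returns p = 1.  Returns
    ``(p_value, exceeds_one)``.
    """
    omegas = np.asarray(profile.omegas, dtype=float)
    if len(omegas) < 2:
        raise ValueError("need at least 2 defined omegas")
    d = omegas - 1.0
    if np.all(d == 0):
        return 1.0, False
    nonzero = d[d != 0]
    if len(nonzero) <= 12:
        p = exact_signed_rank_greater(d)
    else:
        p = float(stats.wilcoxon(nonzero, alternative="greater").pvalue)
    return p, p < alpha


def write_profile_tsv(profiles: Iterable[WindowProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# group\twindow_index\tstart_1based_nt\tn_pairs_used\tn_excluded\tmean\tsem\n"
        )
        for p in profiles:
            fh.write(
                f"{p.group}\t{p.window_index}\t{p.start_nt + 1}\t{p.n_pairs_used}\t"
                f"{p.n_excluded}\t{p.mean:.6g}\t{p.sem:.6g}\n"
            )


def write_comparison_tsv(comparisons: Iterable[WindowComparison], path) -> None:
    with open(path, "w") as fh:
        fh.write("# window_index\tgroup_1\tgroup_2\tstatistic\tp_value\tfold_change\tsignificant\n")
        for c in comparisons:
            fh.write(
                f"{c.window_index}\t{c.label_1}\t{c.label_2}\t{c.statistic:.6g}\t"
                f"{c.p_value:.3g}\t{c.fold_change:.4g}\t{int(c.flag_significant)}\n"
            )
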