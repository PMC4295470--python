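"""Ka/Ks estimation (NG86 and the kappa-weighted approximation), sliding
windows, rank-sum group comparisons and signed-rank tests against 1."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from rlkscan.align import CODON_TO_AA, CodonAlignment, SENSE_CODONS, STOP_CODONS
from rlkscan.records import SeqRecord
from rlkscan.selection import (KaKsError, codon_path_differences, codon_sites,
                               compare_two_windows, compare_window_groups,
                               estimate_kappa, exact_signed_rank_greater,
                               jukes_cantor, kaks_pair, n_windows,
                               window_profile,
                               WindowProfile)
from rlkscan.selection import test_window_vs_one as window_vs_one
from rlkscan.simulate import SimConfig, simulate_family, simulate_pair


def test_single_codon_sites_ttt_hand_enumeration():
    """TTT: only TTC among the nine neighbours is synonymous (Phe), so
    S = 1/3 and N = 8/3."""
    s, n = codon_sites("TTT")
    assert s == pytest.approx(1 / 3)
    assert n == pytest.approx(8 / 3)
    assert s + n == pytest.approx(3.0)


def test_single_difference_ttt_ttc():
    est = kaks_pair(["TTT"], ["TTC"])
    assert est.Sd == pytest.approx(1.0)
    assert est.Nd == pytest.approx(0.0)
    # sites averaged over the two codons; TTC also has S = 1/3
    assert est.S == pytest.approx(1 / 3)
    assert est.N == pytest.approx(8 / 3)


def test_identical_rows_omega_na():
    rows = ["ATG", "AAA", "GCT"]
    est = kaks_pair(rows, rows)
    assert (est.Nd, est.Sd) == (0.0, 0.0)
    assert est.Ka == 0.0 and est.Ks == 0.0
    assert math.isnan(est.omega)


def test_ks_zero_ka_positive_is_inf():
    # AAA (Lys) -> GAA (Glu): one non-synonymous difference, no synonymous
    est = kaks_pair(["AAA", "ATG"], ["GAA", "ATG"])
    assert est.Ka > 0 and est.Ks == 0.0
    assert math.isinf(est.omega)


def test_kaks_symmetry():
    a, b = simulate_pair(60, omega=0.5, kappa=2.0, target_ks=0.4, seed=8)
    e1 = kaks_pair(a, b)
    e2 = kaks_pair(b, a)
    assert e1.defined
    for attr in ("N", "S", "Nd", "Sd", "Ka", "Ks", "omega"):
        assert getattr(e1, attr) == pytest.approx(getattr(e2, attr))


def test_gapped_and_ambiguous_codons_skipped():
    est = kaks_pair(["ATG", "---", "GCN", "AAA"], ["ATG", "AAA", "GCT", "AAA"])
    assert est.n_codons_compared == 2
    assert est.n_codons_skipped == 2


def test_pathways_through_stops_discarded():
    """TGT (Cys) ↔ TGG (Trp) differ at position 3 via TGA (stop)?  No —
    single change, direct.  Use a two-difference pair whose pathways are
    constrained instead: TAT (Tyr) vs TGG (Trp); path TAT→TGG via TAG or
    TGT; TAG is a stop so only the TGT route counts."""
    diffs = codon_path_differences("TAT", "TGG")
    # TAT->TGT (Tyr->Cys, nonsyn), TGT->TGG (Cys->Trp, nonsyn)
    assert diffs == (0.0, 2.0)


def test_zero_comparable_codons_is_error():
    with pytest.raises(KaKsError, match="zero comparable"):
        kaks_pair(["---"], ["ATG"])


def test_jukes_cantor_saturation_flagged():
    with pytest.raises(ValueError):
        jukes_cantor(0.8)


def test_kappa_estimate_from_fourfold_sites():
    # 40 four-fold families, 10 with transition differences at position 3
    pairs = [("GGA", "GGG")] * 10 + [("GGA", "GGA")] * 30
    k = estimate_kappa(pairs)
    assert k > 1.0  # only transitions observed -> kappa above 1
    assert estimate_kappa([("GGA", "GGG")] * 5) == 2.0  # too few sites


def test_ng86_omega_recovery_at_spec_example_conditions():
    """100-codon pairs at ω = 0.2, κ = 2: mean NG86 ω within ±0.1."""
    vals = []
    for rep in range(50):
        a, b = simulate_pair(100, omega=0.2, kappa=2.0, seed=2000 + rep)
        est = kaks_pair(a, b)
        if est.defined:
            vals.append(est.omega)
    assert abs(float(np.mean(vals)) - 0.2) <= 0.1


def test_yn_approx_corrects_transition_bias():
    """Under κ = 2 the kappa-weighted estimator stays within ±0.1 of the
    true ω = 1 where plain NG86 is biased low."""
    vals = []
    for rep in range(50):
        a, b = simulate_pair(100, omega=1.0, kappa=2.0, seed=4000 + rep)
        est = kaks_pair(a, b, method="YN-approx")
        if est.defined:
            vals.append(est.omega)
    assert abs(float(np.mean(vals)) - 1.0) <= 0.1


# ------------------------------------------------------------------- windows

def _alignment_from_codons(rows: dict[str, list[str]]) -> CodonAlignment:
    return CodonAlignment(tuple(
        SeqRecord(id=k, residues="".join(v), alphabet="nt", aligned=True)
        for k, v in rows.items()
    ))


def test_window_count_formula():
    assert n_windows(495) == 29
    assert n_windows(75) == 1
    assert n_windows(74) == 0
    assert n_windows(90) == 2


def test_window_profile_geometry(small_family):
    sim = small_family
    members = next(iter(sim.groups.values()))
    profs = window_profile(sim.alignment, members)
    assert len(profs) == n_windows(sim.alignment.n_columns)
    assert [p.start_nt for p in profs] == [15 * i for i in range(len(profs))]


def test_identical_group_all_windows_na():
    rng = np.random.default_rng(1)
    row = list(rng.choice(SENSE_CODONS, size=30))
    aln = _alignment_from_codons({"a": row, "b": list(row), "c": list(row)})
    profs = window_profile(aln, ["a", "b", "c"])
    for p in profs:
        assert math.isnan(p.mean)
        assert p.n_pairs_used == 0
        assert p.n_excluded == 3


def test_window_shorter_than_alignment_errors():
    rng = np.random.default_rng(2)
    row = list(rng.choice(SENSE_CODONS, size=10))
    aln = _alignment_from_codons({"a": row, "b": list(row)})
    with pytest.raises(ValueError, match="shorter than one window"):
        window_profile(aln, ["a", "b"])
    with pytest.raises(ValueError, match="at least 2 members"):
        window_profile(aln, ["a"], window_nt=30)


# ---------------------------------------------------------------- comparisons

def _profile(label, idx, omegas):
    arr = np.asarray(omegas, dtype=float)
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else float("nan")
    return WindowProfile(label, idx, idx * 15, tuple(omegas),
                         float(arr.mean()) if len(arr) else float("nan"),
                         sem, len(omegas), 0)


def test_identical_omega_lists_not_significant():
    p1 = [_profile("g1", 0, [0.2, 0.3, 0.4])]
    p2 = [_profile("g2", 0, [0.2, 0.3, 0.4])]
    (cmp,) = compare_window_groups(p1, p2)
    assert cmp.p_value == pytest.approx(1.0)
    assert cmp.fold_change == pytest.approx(1.0)
    assert not cmp.flag_significant


def test_complete_separation_n20_significant():
    base = [0.1 + 0.001 * i for i in range(20)]
    p1 = [_profile("g1", 0, [10 * v for v in base])]
    p2 = [_profile("g2", 0, base)]
    (cmp,) = compare_window_groups(p1, p2, alpha=1e-4, fold_min=2.0)
    assert cmp.p_value < 1e-4
    assert cmp.fold_change == pytest.approx(10.0)
    assert cmp.flag_significant


def test_exact_ranksum_matches_enumeration_small_n():
    """Implementation p-value equals full enumeration of rank assignments
    for tie-free samples with n ≤ 10 per side."""
    rng = np.random.default_rng(3)
    for _ in range(5):
        x = list(rng.uniform(0, 1, size=6))
        y = list(rng.uniform(0.2, 1.2, size=5))
        (cmp,) = compare_window_groups([_profile("a", 0, x)], [_profile("b", 0, y)])
        # oracle: enumerate all C(11,6) splits of the pooled ranks
        pooled = sorted(x + y)
        rank = {v: i + 1 for i, v in enumerate(pooled)}
        obs = sum(rank[v] for v in x)
        n_extreme = 0
        combos = list(itertools.combinations(range(1, 12), 6))
        all_sums = [sum(c) for c in combos]
        mean_sum = np.mean(all_sums)
        dev = abs(obs - mean_sum)
        n_extreme = sum(1 for s in all_sums if abs(s - mean_sum) >= dev - 1e-12)
        assert cmp.p_value == pytest.approx(n_extreme / len(combos), abs=1e-12)


def test_underpowered_window_skipped(caplog):
    p1 = [_profile("g1", 0, [0.5])]
    p2 = [_profile("g2", 0, [0.1, 0.2, 0.3])]
    assert compare_window_groups(p1, p2) == []


def test_window_vs_window_within_group():
    profs = [_profile("g", 0, [1.0, 1.2, 1.1, 0.9, 1.3]),
             _profile("g", 1, [0.1, 0.12, 0.11, 0.09, 0.13])]
    cmp = compare_two_windows(profs, 0, 1, alpha=0.05, fold_min=2.0)
    assert cmp.fold_change > 2
    assert cmp.p_value < 0.05
    assert cmp.flag_significant


# ------------------------------------------------------------- window vs one

def test_low_omegas_do_not_exceed_one():
    p, exceeds = window_vs_one(_profile("g", 0, [0.1] * 10))
    assert not exceeds


def test_high_omegas_exact_tail():
    p, exceeds = window_vs_one(_profile("g", 0, [5.0] * 10))
    assert p == pytest.approx(1 / 1024)
    assert exceeds


def test_all_omegas_exactly_one_degenerate():
    p, exceeds = window_vs_one(_profile("g", 0, [1.0] * 6))
    assert p == 1.0 and not exceeds


def test_single_omega_errors():
    with pytest.raises(ValueError):
        window_vs_one(_profile("g", 0, [2.0]))


def test_exact_signed_rank_matches_scipy_tie_free():
    rng = np.random.default_rng(4)
    for _ in range(5):
        d = rng.uniform(-1, 1, size=9)
        d = d[d != 0]
        mine = exact_signed_rank_greater(d)
        ref = float(stats.wilcoxon(d, alternative="greater", method="exact").pvalue)
        assert mine == pytest.approx(ref, abs=1e-12)
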