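"""Kinase subdomain annotation, invariant audit, RD/non-RD classification
and activation-segment consensus matching."""

import numpy as np
import pytest

from rlkscan.motifs import (AnchorOrderError, DEFAULT_MOTIFS, NotAKinaseError,
                            activation_segment_report, annotate,
                            annotate_subdomains, audit_invariants, classify_rd,
                            summarize_families)
from rlkscan.records import SeqRecord
from rlkscan.simulate import ANCHOR_PLAN, SimConfig, canonical_kinase_protein, \
    simulate_family
from rlkscan.align import translate_nt

AA20 = list("ACDEFGHIKLMNPQRSTVWY")


def aa(id_, s):
    return SeqRecord(id=id_, residues=s, alphabet="aa")


def test_canonical_scaffold_anchors_at_planted_offsets(canonical_protein):
    sd = annotate_subdomains(canonical_protein)
    got = {a.subdomain: a.start for a in sd.anchors}
    expected = {sub: off for sub, (off, _m) in ANCHOR_PLAN.items()}
    assert got == expected
    assert sd.span_string == "I → VIII"


def test_canonical_scaffold_has_catalytic_anchors(canonical_protein):
    """The catalytic core anchors (HRD context, DFG, APE) are all found."""
    sd = annotate_subdomains(canonical_protein)
    assert sd.anchor("VIB").text.startswith("HRD")
    assert sd.anchor("VII").text.startswith("DFG")
    assert sd.anchor("VIII").text == "APE"


def test_random_strings_rejected_as_kinase():
    """Chance co-occurrence of ordered anchor motifs in random 200-mers is
    rare: at least 99/100 draws must raise."""
    rng = np.random.default_rng(1)
    rejected = 0
    for k in range(100):
        s = "".join(rng.choice(AA20, size=200))
        try:
            annotate_subdomains(aa(f"r{k}", s))
        except (NotAKinaseError, AnchorOrderError):
            rejected += 1
    assert rejected >= 99


def test_all_invariants_intact_is_typical(canonical_protein):
    sd = annotate_subdomains(canonical_protein)
    checks, kclass = audit_invariants(canonical_protein, sd)
    assert kclass == "typical"
    assert not any(c.is_mismatch for c in checks)


def test_dfg_to_dfa_edit_is_atypical(canonical_protein):
    s = list(canonical_protein.residues)
    dfg_off = ANCHOR_PLAN["VII"][0]
    assert s[dfg_off + 2] == "G"
    s[dfg_off + 2] = "A"
    rec = aa("edited", "".join(s))
    ann = annotate(rec)
    assert ann.kinase_class == "atypical"
    mismatches = [c for c in ann.invariant_audit if c.is_mismatch]
    assert len(mismatches) == 1
    assert (mismatches[0].expected, mismatches[0].observed) == ("G", "A")


def test_fragment_ending_before_dfg_reports_not_spanned(canonical_protein):
    truncated = aa("trunc", canonical_protein.residues[:ANCHOR_PLAN["VII"][0]])
    sd = annotate_subdomains(truncated)
    checks, kclass = audit_invariants(truncated, sd)
    assert kclass == "typical"
    assert any(c.subdomain == "VII" and c.observed == "not spanned" for c in checks)


def test_rd_and_nonrd_contexts():
    base = canonical_kinase_protein(rd=True)
    sd = annotate_subdomains(aa("rd", base))
    assert classify_rd(aa("rd", base), sd) == ("RD", None)
    non = canonical_kinase_protein(rd=False)
    sd2 = annotate_subdomains(aa("non", non))
    assert classify_rd(aa("non", non), sd2) == ("nonRD", "C")


def test_truncation_before_vib_is_undetermined(canonical_protein):
    truncated = aa("t", canonical_protein.residues[:ANCHOR_PLAN["VIB"][0] - 5])
    sd = annotate_subdomains(truncated)
    assert classify_rd(truncated, sd) == ("undetermined", None)


def test_rd_classification_partition_on_simulator(four_group_family):
    """classify_rd recovers every planted RD/non-RD label; the class triple
    is a partition and the substituent is never 'R'."""
    sim = four_group_family
    for group, members in sim.groups.items():
        for m in members:
            prot = aa(m, translate_nt(sim.alignment[m].ungapped))
            ann = annotate(prot)
            assert ann.catalytic_class == sim.rd_labels[group]
            assert ann.catalytic_class in ("RD", "nonRD", "undetermined")
            if ann.rd_substituent is not None:
                assert ann.rd_substituent != "R"
                assert ann.catalytic_class == "nonRD"


def test_out_of_order_anchor_raises_with_positions():
    # DFG context placed before the catalytic loop, with no second DFG later
    s = (
        "QTWMCHPSQT" + "GEGSFG" + "QTWMCHPS" + "VAVK"
        + "QT" + "DFGLA" + "TWMCHPSQTWMC" + "HRDLKPSN" + "QTWMCHPS" * 6
    )
    with pytest.raises(AnchorOrderError, match="before"):
        annotate_subdomains(aa("x", s))


def test_activation_segment_report_matches_key_positions(canonical_protein):
    ann = annotate(canonical_protein)
    seqs = {ann.seq_id: canonical_protein}
    df = activation_segment_report([ann], seqs)
    assert set(df["motif"]) == {m.name for m in DEFAULT_MOTIFS}
    row = df[df.motif == "Pto_190_215"].iloc[0]
    assert row["spanned"]
    # the scaffold carries D of DFG; key S/T positions fall in background
    assert row["n_matched"] >= 1
    assert len(row["match_string"]) == row["n_positions"]


def test_activation_segment_threonine_match(canonical_protein):
    """A Thr planted at the position homologous to the Pto P+1-loop
    threonine is reported as matched."""
    s = list(canonical_protein.residues)
    dfg = ANCHOR_PLAN["VII"][0]
    s[dfg + 8], s[dfg + 9], s[dfg + 14] = "S", "T", "T"
    rec = aa("thr", "".join(s))
    ann = annotate(rec)
    df = activation_segment_report([ann], {"thr": rec})
    row = df[df.motif == "Pto_190_215"].iloc[0]
    assert row["n_matched"] == row["n_positions"]
    assert "X" not in row["match_string"]


def test_sequence_lacking_ape_is_flagged(canonical_protein):
    truncated = aa("noape", canonical_protein.residues[:ANCHOR_PLAN["VIII"][0]])
    ann = annotate(truncated)
    df = activation_segment_report([ann], {"noape": truncated})
    assert not df["spanned"].any()
    assert (df["match_string"] == "not spanned").all()


def test_family_summary_counts_and_identity(small_family):
    sim = small_family
    annotations = []
    seqs = {}
    for members in sim.groups.values():
        for m in members:
            nt_rec = SeqRecord(id=m, residues=sim.alignment[m].ungapped, alphabet="nt")
            seqs[m] = nt_rec
            annotations.append(annotate(aa(m, translate_nt(nt_rec.residues))))
    assignments = {m: g for g, ms in sim.groups.items() for m in ms}
    df = summarize_families(annotations, assignments, seqs)
    assert set(df["group"]) == set(sim.groups)
    for _, row in df.iterrows():
        assert row["n"] == len(sim.groups[row["group"]])
        assert 0 <= row["aa_identity_min"] <= row["aa_identity_max"] <= 100
        expected_nonrd = len(sim.groups[row["group"]]) \
            if sim.rd_labels[row["group"]] == "nonRD" else 0
        assert row["n_nonRD"] == expected_nonrd


def test_identical_group_identity_range_is_100(canonical_protein):
    from rlkscan.simulate import SimConfig, simulate_family

    sim = simulate_family(SimConfig(
        n_groups=2, members_per_group=3, seed=3,
        between_group_branch=0.0, within_group_branch=0.0,
    ))
    annotations = []
    seqs = {}
    for members in sim.groups.values():
        for m in members:
            nt_rec = SeqRecord(id=m, residues=sim.alignment[m].ungapped, alphabet="nt")
            seqs[m] = nt_rec
            annotations.append(annotate(aa(m, translate_nt(nt_rec.residues))))
    assignments = {m: g for g, ms in sim.groups.items() for m in ms}
    df = summarize_families(annotations, assignments, seqs)
    assert (df["aa_identity_min"] == 100.0).all()
    assert (df["nt_identity_max"] == 100.0).all()


def test_unlabeled_sequence_listed_unassigned(canonical_protein):
    ann = annotate(canonical_protein)
    seqs = {ann.seq_id: SeqRecord(
        id=ann.seq_id,
        residues="ATG" * len(canonical_protein.residues), alphabet="nt")}
    # no assignment for this id -> "unassigned" row
    df = summarize_families([ann], {}, seqs)
    assert list(df["group"]) == ["unassigned"]
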