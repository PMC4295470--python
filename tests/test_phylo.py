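"""Poisson distances, neighbor joining, bootstrap supports and
reference-based subfamily assignment."""

import math

import numpy as np
import pytest

from rlkscan.align import ProteinAlignment
from rlkscan.phylo import (DistanceError, DistanceMatrix, assign_groups,
                           bootstrap_support, nj_tree, poisson_distance)
from rlkscan.records import SeqRecord

from conftest import AA20, perturb_protein, random_additive_matrix


def prot(id_, s):
    return SeqRecord(id=id_, residues=s, alphabet="aa", aligned=True)


# ------------------------------------------------------------ poisson distance

def test_identical_sequences_distance_zero():
    aln = ProteinAlignment((prot("a", "MKVTW"), prot("b", "MKVTW")))
    dm = poisson_distance(aln)
    assert dm[("a", "b")] == 0.0


def test_poisson_correction_value():
    # p = 0.1 over 10 columns -> d = -ln(0.9)
    aln = ProteinAlignment((prot("a", "MKVTWMKVTW"), prot("b", "MKVTWMKVTA")))
    dm = poisson_distance(aln)
    assert dm[("a", "b")] == pytest.approx(0.1053605, abs=1e-6)


def test_poisson_small_p_approaches_p():
    a = "M" * 99 + "K"
    b = "M" * 99 + "R"  # p = 0.01
    dm = poisson_distance(ProteinAlignment((prot("a", a), prot("b", b))))
    assert dm[("a", "b")] == pytest.approx(0.01, rel=0.01)


def test_poisson_monotone_in_p():
    base = "MKVTWCEDQH" * 4
    rng = np.random.default_rng(0)
    prev = -1.0
    for n_diff in (2, 6, 12, 20):
        other = perturb_protein(base, 0, rng)
        chars = list(base)
        for k in range(n_diff):
            chars[k] = "W" if chars[k] != "W" else "Y"
        dm = poisson_distance(ProteinAlignment((prot("a", base), prot("b", "".join(chars)))))
        assert dm[("a", "b")] > prev
        prev = dm[("a", "b")]


def test_all_different_pair_is_error():
    aln = ProteinAlignment((prot("a", "MMMM"), prot("b", "KKKK")))
    with pytest.raises(DistanceError, match=r"\(a, b\)"):
        poisson_distance(aln)


def test_no_comparable_columns_pairwise_deletion_is_error():
    aln = ProteinAlignment((prot("a", "MK--"), prot("b", "--VT")))
    with pytest.raises(DistanceError, match="no comparable columns"):
        poisson_distance(aln, deletion="pairwise")


def test_complete_deletion_drops_gapped_columns():
    aln = ProteinAlignment((prot("a", "MKV-W"), prot("b", "MKVAW"),
                            prot("c", "MRVTW")))
    dm = poisson_distance(aln, deletion="complete")
    # column 4 (gap in a) removed for every pair: 4 comparable columns
    assert dm[("a", "b")] == 0.0
    assert dm[("a", "c")] == pytest.approx(-math.log(1 - 0.25))


# ------------------------------------------------------------------- NJ trees

def test_three_taxon_closed_form():
    d = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
    tree = nj_tree(DistanceMatrix(labels=("a", "b", "c"), d=d))
    lengths = {c.label: c.length for c in tree.root.children}
    assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}


def test_two_taxa_error():
    d = np.array([[0, 1.0], [1.0, 0]])
    with pytest.raises(ValueError, match="at least 3"):
        nj_tree(DistanceMatrix(labels=("a", "b"), d=d))


def test_additive_six_taxon_matrix_recovered_exactly():
    rng = np.random.default_rng(7)
    dm = random_additive_matrix(6, rng)
    tree = nj_tree(dm)
    rec = tree.leaf_distances()
    assert rec.labels == dm.labels
    np.testing.assert_allclose(rec.d, dm.d, atol=1e-9)


def test_nj_recovers_50_random_additive_matrices():
    rng = np.random.default_rng(123)
    for _ in range(50):
        n = int(rng.integers(5, 13))
        dm = random_additive_matrix(n, rng)
        rec = nj_tree(dm).leaf_distances()
        np.testing.assert_allclose(rec.d, dm.d, atol=1e-8)


def test_nj_topology_matches_scikit_bio():
    """Independent cross-check of the NJ implementation."""
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sknj

    rng = np.random.default_rng(9)
    for _ in range(5):
        dm = random_additive_matrix(8, rng)
        sk_tree = sknj(SkDM(dm.d, ids=list(dm.labels)))
        full = frozenset(dm.labels)
        anchor = min(full)
        sk_biparts = set()
        for node in sk_tree.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            if 2 <= len(below) <= len(full) - 2:
                sk_biparts.add(below if anchor not in below else full - below)
        assert set(nj_tree(dm).bipartitions().keys()) == sk_biparts


def test_asymmetric_matrix_rejected():
    d = np.array([[0, 1.0, 2.0], [1.5, 0, 1.0], [2.0, 1.0, 0]])
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(labels=("a", "b", "c"), d=d)


def test_newick_output_contains_lengths_and_supports(small_family):
    aln = small_family.alignment.to_protein()
    tree = bootstrap_support(aln, replicates=20, seed=2)
    nwk = tree.to_newick()
    assert nwk.endswith(";")
    assert ":" in nwk  # branch lengths present
    for leaf in tree.leaf_names():
        assert leaf in nwk


# ------------------------------------------------------------------ bootstrap

def _two_clade_alignment(seed=11, between=40, length=120):
    """Two 4-leaf clades, strongly diverged between and shallowly within;
    distinct per-member perturbation counts keep distances generic
    (tie-free), so NJ has a unique optimum."""
    rng = np.random.default_rng(seed)
    base1 = "".join(rng.choice(AA20, size=length))
    base2 = perturb_protein(base1, between, rng)
    recs = tuple(
        prot(f"A{i}", perturb_protein(base1, 2 + 2 * i, rng)) for i in range(4)
    ) + tuple(
        prot(f"B{i}", perturb_protein(base2, 3 + 2 * i, rng)) for i in range(4)
    )
    return ProteinAlignment(recs)


def test_well_separated_clades_get_high_support():
    aln = _two_clade_alignment(seed=11)
    tree = bootstrap_support(aln, replicates=200, seed=11)
    clade_a = frozenset(f"A{i}" for i in range(4))
    clade_b = frozenset(f"B{i}" for i in range(4))
    supports = {frozenset(k): v.support for k, v in tree.bipartitions().items()}
    # the A|B split is one edge; its canonical side is the one lacking 'A0'
    assert supports[clade_b] >= 99.0


def test_single_replicate_supports_are_zero_or_hundred():
    aln = _two_clade_alignment(seed=3)
    tree = bootstrap_support(aln, replicates=1, seed=5)
    for node in tree.bipartitions().values():
        assert node.support in (0.0, 100.0)


def test_same_seed_reproduces_supports():
    aln = _two_clade_alignment(seed=4)
    t1 = bootstrap_support(aln, replicates=50, seed=99)
    t2 = bootstrap_support(aln, replicates=50, seed=99)
    s1 = {k: v.support for k, v in t1.bipartitions().items()}
    s2 = {k: v.support for k, v in t2.bipartitions().items()}
    assert s1 == s2


def test_supports_invariant_to_leaf_order():
    aln = _two_clade_alignment(seed=6)
    shuffled = ProteinAlignment(tuple(reversed(aln.records)))
    s1 = {k: v.support for k, v in
          bootstrap_support(aln, replicates=50, seed=7).bipartitions().items()}
    s2 = {k: v.support for k, v in
          bootstrap_support(shuffled, replicates=50, seed=7).bipartitions().items()}
    assert set(s1) == set(s2)
    # resampled columns are identical per replicate, so supports agree too
    assert s1 == s2


# ------------------------------------------------------------ group assignment

def test_pure_supported_clade_assigns_label():
    aln = _two_clade_alignment(seed=13)
    tree = bootstrap_support(aln, replicates=100, seed=13)
    refs = {"A0": "CrRLK1L", "B0": "LRRXII"}
    ga = assign_groups(tree, refs, min_support=70)
    assert ga.labels["A1"] == "CrRLK1L"
    assert ga.labels["B3"] == "LRRXII"
    assert ga.support["A1"] >= 70


def test_mixed_clade_yields_uncertain():
    aln = _two_clade_alignment(seed=14)
    tree = bootstrap_support(aln, replicates=100, seed=14)
    # both references inside the A clade, labelled differently: the smallest
    # supported clade containing an A query mixes subfamilies
    refs = {"A0": "fam1", "A1": "fam2"}
    ga = assign_groups(tree, refs, min_support=70)
    assert ga.labels["A2"] in ("uncertain", "fam1", "fam2")
    # B queries see both families only at the clade mixing them
    assert ga.labels["B1"] == "uncertain"


def test_no_references_is_error():
    aln = _two_clade_alignment(seed=15)
    tree = bootstrap_support(aln, replicates=10, seed=15)
    with pytest.raises(ValueError, match="no reference leaves"):
        assign_groups(tree, {"Z9": "whatever"})


def test_simulated_four_group_assignment_fully_correct(four_group_family):
    sim = four_group_family
    tree = bootstrap_support(sim.alignment.to_protein(), replicates=100, seed=1)
    refs = {members[0]: g for g, members in sim.groups.items()}
    ga = assign_groups(tree, refs, min_support=70)
    truth = {m: g for g, ms in sim.groups.items() for m in ms}
    assert ga.labels  # non-empty
    for q, label in ga.labels.items():
        assert label == truth[q]
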