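"""Subfamily cascade, subgroup rules, identity distances and NJ trees."""

from collections import Counter

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from conftest import (
    best_leastsquares_topology,
    random_additive_tree,
    tree_distances,
    tree_splits,
    treenode_splits,
)
from mipscan.classify import (
    assign_subfamily,
    assign_subgroup,
    identity_matrix,
    nj_tree,
)
from mipscan.core import UNCLASSIFIED, AqpProfile, ProteinRecord


def _profile(arr=None, npa=("NPA", "NPA"), froger=None, pid="x"):
    arr = arr or {}
    froger = froger or {}
    return AqpProfile(
        protein_id=pid,
        npa_lb=npa[0], npa_le=npa[1],
        arr={p: arr.get(p) for p in ("H2", "H5", "LE1", "LE2")},
        froger={p: froger.get(p) for p in ("P1", "P2", "P3", "P4", "P5")},
    )


class TestSubfamilyCascade:
    def test_reproduces_reference_family_labels(self, profiles):
        """All 37 reference proteins classify to the subfamily in their name."""
        labels = {p.protein_id: assign_subfamily(p).label for p in profiles}
        assert all(lab == pid[2:5] for pid, lab in labels.items())
        assert Counter(labels.values()) == {
            "PIP": 10, "TIP": 9, "NIP": 8, "XIP": 6, "SIP": 4}

    def test_every_fixture_profile_fires_exactly_one_rule(self, profiles):
        for p in profiles:
            trace = assign_subfamily(p)
            assert trace.label != UNCLASSIFIED
            assert trace.fired_rule is not None
            assert trace.evidence

    def test_pip_signature(self):
        trace = assign_subfamily(_profile(
            arr={"H2": "F", "H5": "H", "LE1": "T", "LE2": "R"},
            froger={"P1": "E", "P2": "S", "P3": "A", "P4": "F", "P5": "W"}))
        assert trace.label == "PIP"

    def test_tip_signature(self):
        trace = assign_subfamily(_profile(
            arr={"H2": "N", "H5": "V", "LE1": "G", "LE2": "C"},
            froger={"P1": "A", "P2": "A", "P3": "A", "P4": "Y", "P5": "W"}))
        assert trace.label == "TIP"

    def test_truncated_xip_classified_from_first_motif(self):
        trace = assign_subfamily(_profile(
            arr={"H2": "V"}, npa=("SPV", None), froger={"P1": "M"}))
        assert trace.label == "XIP"

    def test_all_missing_profile_is_unclassified(self):
        trace = assign_subfamily(_profile(npa=(None, None)))
        assert trace.label == UNCLASSIFIED
        assert trace.fired_rule is None
        assert trace.evidence == []


class TestSubgroups:
    @pytest.mark.parametrize("arr,expected", [
        (("W", "V", "A", "R"), "NIP I"),
        (("W", "A", "A", "R"), "NIP I"),
        (("G", "S", "G", "R"), "NIP III"),
    ])
    def test_nip_arr_subgroups(self, arr, expected):
        p = _profile(arr=dict(zip(("H2", "H5", "LE1", "LE2"), arr)))
        assert assign_subgroup(p, subfamily="NIP") == expected

    def test_nip_ii_from_variant_motifs(self):
        p = _profile(arr={"H2": "A", "H5": "I", "LE1": "G", "LE2": "R"},
                     npa=("NPS", "NPV"))
        assert assign_subgroup(p, subfamily="NIP") == "NIP II"

    @pytest.mark.parametrize("arr,expected", [
        (("V", "F", "V", "R"), "XIP1"),
        (("I", "F", "V", "R"), "XIP2"),
        (("V", "Y", "A", "R"), "XIP3"),
    ])
    def test_xip_arr_subgroups(self, arr, expected):
        p = _profile(arr=dict(zip(("H2", "H5", "LE1", "LE2"), arr)))
        assert assign_subgroup(p, subfamily="XIP") == expected

    def test_incomplete_xip_prefix_match(self):
        p = _profile(arr={"H2": "V"}, npa=("SPV", None))
        assert assign_subgroup(p, subfamily="XIP") == "XIP1"

    def test_reference_family_subgroups(self, profiles):
        expected = {
            "RcNIP1;1": "NIP I", "RcNIP3;1": "NIP I", "RcNIP4;1": "NIP I",
            "RcNIP4;2": "NIP I", "RcNIP2;1": "NIP III",
            "RcNIP5;1": "NIP II", "RcNIP6;1": "NIP II", "RcNIP7;1": "NIP II",
            "RcXIP1;1": "XIP1", "RcXIP1;2": "XIP1", "RcXIP1;3": "XIP1",
            "RcXIP1;4": "XIP1", "RcXIP2;1": "XIP2", "RcXIP3;1": "XIP3",
        }
        for p in profiles:
            if p.protein_id in expected:
                label = assign_subfamily(p).label
                assert assign_subgroup(p, subfamily=label) == \
                    expected[p.protein_id]

    def test_unclassified_profile_raises(self):
        with pytest.raises(ValueError):
            assign_subgroup(_profile(), subfamily=UNCLASSIFIED)


class TestIdentityMatrix:
    def test_identical_sequences_distance_zero(self):
        recs = [ProteinRecord(id="a", residues="MKVLAW"),
                ProteinRecord(id="b", residues="MKVLAW")]
        assert identity_matrix(recs)["a", "b"] == 0.0

    def test_single_mismatch_identity(self):
        recs = [ProteinRecord(id="a", residues="AAAA"),
                ProteinRecord(id="b", residues="AAAT")]
        assert identity_matrix(recs)["a", "b"] == pytest.approx(0.25)

    def test_matrix_symmetric_for_synthetic_family(self):
        from mipscan.synthetic import gen_family

        recs, _ = gen_family(n_per_subfamily=1, mutation_rate=0.2, seed=4)
        dm = identity_matrix(recs)
        assert np.allclose(dm.data, dm.data.T)
        assert np.all(np.diag(dm.data) == 0)
        assert np.all((dm.data >= 0) & (dm.data <= 1))

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            identity_matrix([ProteinRecord(id="a", residues="MKV")])


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                                     dtype=float), ids=list("abc"))
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_four_taxa_additive_recovery_vs_bruteforce(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            edges, lengths, leaves = random_additive_tree(4, rng)
            d = tree_distances(edges, lengths, leaves)
            names = [f"t{i}" for i in leaves]
            nj = nj_tree(DistanceMatrix(d, ids=names))
            truth = {frozenset(names[i] for i in part)
                     for part in tree_splits(edges, leaves)}
            assert treenode_splits(nj) == truth
            assert best_leastsquares_topology(d, names) == truth

    def test_ultrametric_four_taxa_sister_pairs(self):
        # ((a,b),(c,d)) with heights 1 and 3
        d = np.array([[0, 2, 6, 6], [2, 0, 6, 6],
                      [6, 6, 0, 2], [6, 6, 2, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(d, ids=list("abcd")))
        assert treenode_splits(tree) == {frozenset({"c", "d"})}

    def test_five_taxa_additive_recovery_and_skbio_agreement(self):
        rng = np.random.default_rng(23)
        for _ in range(4):
            edges, lengths, leaves = random_additive_tree(5, rng)
            d = tree_distances(edges, lengths, leaves)
            names = [f"t{i}" for i in leaves]
            dm = DistanceMatrix(d, ids=names)
            ours = nj_tree(dm)
            truth = {frozenset(names[i] for i in part)
                     for part in tree_splits(edges, leaves)}
            assert treenode_splits(ours) == truth
            assert best_leastsquares_topology(d, names) == truth
            reference = skbio_nj(dm)
            assert treenode_splits(reference) == truth

    def test_branch_lengths_recovered_on_additive_input(self):
        rng = np.random.default_rng(5)
        edges, lengths, leaves = random_additive_tree(5, rng)
        d = tree_distances(edges, lengths, leaves)
        names = [f"t{i}" for i in leaves]
        tree = nj_tree(DistanceMatrix(d, ids=names))
        # pairwise path lengths on the NJ tree reproduce the input distances
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                ta = tree.find(a)
                assert ta.distance(tree.find(b)) == pytest.approx(
                    d[names.index(a), names.index(b)])

    def test_nonnegative_branch_lengths(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0.2, 1.0, size=(6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tree = nj_tree(DistanceMatrix(d, ids=[f"x{i}" for i in range(6)]))
        for node in tree.traverse(include_self=False):
            assert node.length >= 0

    def test_asymmetric_matrix_rejected(self):
        from skbio import DistanceMatrix as DM

        with pytest.raises(Exception):
            DM(np.array([[0, 1], [2, 0]], dtype=float), ids=["a", "b"])

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            nj_tree(dm)
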