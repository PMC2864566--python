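"""Fitch reconstruction, NG86 rates, Dollo placement and T_N."""

import itertools
import math
import warnings

import dendropy
import numpy as np
import pytest

from unipseudo.io_model import (
    ValidationError,
    species_tree_from_dendropy,
)
from unipseudo.evolution_dating import (
    estimate_tn,
    estimate_tn_from_alignment,
    fitch_ancestral_reconstruction,
    lineage_omega,
    nei_gojobori_kaks,
    place_disruption,
)
from unipseudo.synthetic_data import simulate_codon_phylogeny

_SENSE = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _tree(newick):
    return species_tree_from_dendropy(
        dendropy.Tree.get(data=newick, schema="newick")
    )


class TestFitch:
    def test_identical_leaves_identical_ancestors(self, primate_tree):
        seq = "ACGTACGT"
        aln = {sp: seq for sp in primate_tree.leaf_labels()}
        anc, changes = fitch_ancestral_reconstruction(aln, primate_tree)
        assert changes == 0
        assert all(s == seq for s in anc.values())

    def test_single_difference_single_change(self):
        tree = _tree("((a:1,b:1):1,(c:1,d:1):1);")
        aln = {"a": "AAA", "b": "AAA", "c": "AAA", "d": "ATA"}
        _, changes = fitch_ancestral_reconstruction(aln, tree)
        assert changes == 1

    def test_parsimony_count_matches_brute_force(self):
        # exhaustive minimum over all internal labelings, <=5 leaves
        tree = _tree("(((a:1,b:1):1,c:2):1,(d:2,e:2):1);")
        leaves = ["a", "b", "c", "d", "e"]
        internal = [
            n for n in tree.tree.postorder_node_iter()
            if not n.is_leaf()
        ]
        edges = [
            (n, c) for n in internal for c in n.child_nodes()
        ]
        rng = np.random.default_rng(8)
        for _ in range(5):
            n_sites = int(rng.integers(1, 10))
            aln = {
                lf: "".join(rng.choice(list("ACGT"), size=n_sites))
                for lf in leaves
            }
            _, fitch_count = fitch_ancestral_reconstruction(aln, tree)
            brute = 0
            for site in range(n_sites):
                best = math.inf
                for labels in itertools.product(
                    "ACGT", repeat=len(internal)
                ):
                    assign = dict(zip(internal, labels))
                    cost = 0
                    for parent, child in edges:
                        a = assign[parent]
                        b = (
                            assign[child]
                            if child in assign
                            else aln[child.taxon.label][site]
                        )
                        cost += a != b
                    best = min(best, cost)
                brute += best
            assert fitch_count == brute

    def test_species_missing_from_tree_rejected(self, primate_tree):
        with pytest.raises(ValidationError, match="mouse"):
            fitch_ancestral_reconstruction(
                {"human": "AAA", "mouse": "AAA"}, primate_tree
            )


class TestNeiGojobori:
    def test_identical_sequences_zero(self):
        r = nei_gojobori_kaks("ATGGCT", "ATGGCT")
        assert (r.ka, r.ks) == (0.0, 0.0)

    def test_hand_computed_synonymous_oracle(self):
        # GGG vs GGA: S = 2 sites, one synonymous difference, p_s = 0.5
        r = nei_gojobori_kaks("GGGGGG", "GGAGGG")
        assert r.ka == 0.0
        assert r.ks == pytest.approx(
            -0.75 * math.log(1 / 3), abs=1e-12
        )

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(3, 20))
            s1 = "".join(
                _SENSE[i] for i in rng.integers(0, 61, n)
            )
            s2 = "".join(
                _SENSE[i] for i in rng.integers(0, 61, n)
            )
            a = nei_gojobori_kaks(s1, s2)
            b = nei_gojobori_kaks(s2, s1)
            assert a.ka == pytest.approx(b.ka, abs=1e-12)
            assert a.ks == pytest.approx(b.ks, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            nei_gojobori_kaks("ATG", "ATGGCT")

    def test_saturation_flagged(self):
        # maximally different codons push p beyond the JC domain
        s1 = "GGG" * 30
        s2 = "CCC" * 30
        r = nei_gojobori_kaks(s1, s2)
        assert r.saturated

    def test_agrees_with_biopython_reference(self):
        codonalign = pytest.importorskip("Bio.codonalign.codonseq")
        rng = np.random.default_rng(10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(10):
                c1 = [_SENSE[i] for i in rng.integers(0, 61, 50)]
                c2 = list(c1)
                for _ in range(8):
                    i = int(rng.integers(50))
                    cand = list(c2[i])
                    cand[int(rng.integers(3))] = "ACGT"[
                        int(rng.integers(4))
                    ]
                    if "".join(cand) not in ("TAA", "TAG", "TGA"):
                        c2[i] = "".join(cand)
                s1, s2 = "".join(c1), "".join(c2)
                mine = nei_gojobori_kaks(s1, s2)
                dn, ds = codonalign.cal_dn_ds(
                    codonalign.CodonSeq(s1),
                    codonalign.CodonSeq(s2),
                    method="NG86",
                )
                assert mine.ka == pytest.approx(dn, abs=1e-9)
                assert mine.ks == pytest.approx(ds, abs=1e-9)


class TestLineageOmega:
    def test_neutral_long_branches_near_one(self, primate_tree):
        # branches long enough to accumulate hundreds of substitutions
        hits = total = 0
        for seed in range(12):
            leaves, _ = simulate_codon_phylogeny(
                primate_tree, 1.0, 10_000, seed=seed,
                neutral_rate=0.004,
            )
            rates = lineage_omega(leaves, primate_tree)
            for b in rates.branches:
                if b.child in ("marmoset", "rhesus"):  # >=20 MY
                    total += 1
                    hits += 0.9 <= b.omega <= 1.1
        assert hits / total >= 0.95

    def test_constrained_omega_recovered(self, primate_tree):
        leaves, _ = simulate_codon_phylogeny(
            primate_tree, 0.1, 10_000, seed=3
        )
        rates = lineage_omega(leaves, primate_tree)
        b = rates.branch_for("marmoset")
        assert 0.05 <= b.omega <= 0.2

    def test_zero_divergence_branch_flagged_undefined(
        self, primate_tree
    ):
        aln = {
            sp: "ATGGCTAAG" * 10
            for sp in primate_tree.leaf_labels()
        }
        rates = lineage_omega(aln, primate_tree)
        for b in rates.branches:
            assert b.ka == 0.0 and b.ks == 0.0
            assert b.omega is None


class TestDollo:
    def test_human_only_maps_to_terminal_branch(self, primate_tree):
        p = place_disruption({"human": "present"}, primate_tree)
        assert p.branch == "human"
        assert not p.homoplasic

    def test_catarrhine_pattern_maps_to_stem(self, primate_tree):
        # the NR1H5 sharing pattern: human+chimp+rhesus, not marmoset
        p = place_disruption(
            {
                "human": "present",
                "chimp": "present",
                "rhesus": "present",
                "marmoset": "absent",
            },
            primate_tree,
        )
        assert p.branch == "chimp+human+rhesus"
        assert not p.homoplasic

    def test_all_present_maps_to_root(self, primate_tree):
        p = place_disruption(
            {sp: "present" for sp in primate_tree.leaf_labels()},
            primate_tree,
        )
        assert set(p.clade_leaves) == set(primate_tree.leaf_labels())

    def test_absent_inside_clade_flags_homoplasy(self, primate_tree):
        p = place_disruption(
            {
                "human": "present",
                "chimp": "absent",
                "rhesus": "present",
            },
            primate_tree,
        )
        assert p.homoplasic
        assert p.conflicting_species == ("chimp",)

    def test_missing_species_uninformative(self, primate_tree):
        p = place_disruption(
            {
                "human": "present",
                "chimp": "present",
                "rhesus": "missing",
                "marmoset": "missing",
            },
            primate_tree,
        )
        assert p.branch == "chimp+human"

    def test_empty_pattern_rejected(self, primate_tree):
        with pytest.raises(ValidationError):
            place_disruption({}, primate_tree)

    def test_recovers_planted_branch_for_every_clade(
        self, primate_tree
    ):
        all_leaves = set(primate_tree.leaf_labels())
        for node in primate_tree.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            clade = primate_tree.leaves_under(node)
            pattern = {
                sp: "present" if sp in clade else "absent"
                for sp in all_leaves
            }
            p = place_disruption(pattern, primate_tree)
            assert set(p.clade_leaves) == clade
            assert not p.homoplasic


class TestEstimateTn:
    def test_fully_neutral_history_gives_t(self):
        est = estimate_tn(1.0, 0.12, t=6.6)
        assert est.t_n == pytest.approx(6.6, abs=1e-12)

    def test_fully_constrained_history_gives_zero(self):
        est = estimate_tn(0.12, 0.12, t=6.6)
        assert est.t_n == pytest.approx(0.0, abs=1e-12)

    def test_worked_value(self):
        # 6.6 x (0.56 - 0.12) / (1 - 0.12) = 3.3 MY
        est = estimate_tn(0.56, 0.12, t=6.6)
        assert est.t_n == pytest.approx(3.3, abs=1e-9)

    def test_neutral_background_rejected(self):
        with pytest.raises(ValidationError):
            estimate_tn(0.5, 1.0)

    def test_monotone_in_omega1(self):
        vals = [
            estimate_tn(w, 0.12, t=6.6).t_n
            for w in np.linspace(0.12, 1.0, 20)
        ]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_clamping_flagged(self):
        est = estimate_tn(0.05, 0.12, t=6.6)
        assert est.t_n == 0.0 and est.clamped
        est = estimate_tn(1.5, 0.12, t=6.6)
        assert est.t_n == 6.6 and est.clamped

    def test_light_parameter_recovery(self, primate_tree):
        # single-replicate sanity check; the full 50-replicate study
        # runs in the acceptance suite
        leaves, rec = simulate_codon_phylogeny(
            primate_tree, 0.12, 5000,
            switch_branch="human", t_n=3.3, seed=77,
        )
        est = estimate_tn_from_alignment(leaves, primate_tree, "human")
        assert abs(est.t_n - 3.3) < 2.5
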