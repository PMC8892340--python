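import numpy as np
import pandas as pd
import pytest

from conftest import make_states
from oracles import brute_force_dollo

from coevotrait.gene_status import (
    CallConfig,
    GeneStatusCall,
    binarize,
    call_status,
    count_losses,
    thin_tree,
)
from coevotrait.phylo import TreeError, parse_newick
from coevotrait.simulate import simulate_tree, simulate_trait
from coevotrait.ctmc import RateSpec2
from coevotrait.traits import TraitStates


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["species", "gene", "domain", "evalue"])


PRDM9_CONFIG = CallConfig(required_domains={"PRDM9": frozenset({"KRAB", "SET"})})


class TestCallStatus:
    def test_both_required_domains_pass(self):
        hits = hits_frame([("hs", "PRDM9", "KRAB", 1e-6), ("hs", "PRDM9", "SET", 1e-10)])
        calls = call_status(hits, PRDM9_CONFIG, "PRDM9")
        assert calls["hs"].status == "complete"

    def test_one_of_two_domains_is_partial(self):
        hits = hits_frame([("hs", "PRDM9", "SET", 1e-10)])
        assert call_status(hits, PRDM9_CONFIG, "PRDM9")["hs"].status == "partial"

    def test_domain_above_presence_threshold_fails(self):
        hits = hits_frame([("hs", "PRDM9", "KRAB", 0.5), ("hs", "PRDM9", "SET", 1e-10)])
        assert call_status(hits, PRDM9_CONFIG, "PRDM9")["hs"].status == "partial"

    def test_domain_between_thresholds_detectable_but_incomplete(self):
        # present at 0.1 but failing the 1e-4 completeness cut
        hits = hits_frame([("hs", "PRDM9", "KRAB", 1e-2), ("hs", "PRDM9", "SET", 1e-10)])
        assert call_status(hits, PRDM9_CONFIG, "PRDM9")["hs"].status == "partial"

    def test_species_without_rows_absent(self):
        hits = hits_frame([("hs", "PRDM9", "KRAB", 1e-6), ("hs", "PRDM9", "SET", 1e-6)])
        calls = call_status(hits, PRDM9_CONFIG, "PRDM9", species=["hs", "mm"])
        assert calls["mm"].status == "absent"

    def test_domainless_gene_called_from_hits_alone(self):
        config = CallConfig(required_domains={}, domainless_genes=frozenset({"MEI1"}))
        hits = hits_frame([("hs", "MEI1", "none", 1e-8)])
        calls = call_status(hits, config, "MEI1", species=["hs", "mm"])
        assert calls["hs"].status == "complete"
        assert calls["mm"].status == "absent"

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError):
            call_status(hits_frame([]), PRDM9_CONFIG, "ZCWPW1")


class TestBinarize:
    def test_mapping(self):
        calls = {
            "a": GeneStatusCall("a", "g", "complete"),
            "b": GeneStatusCall("b", "g", "partial"),
            "c": GeneStatusCall("c", "g", "absent"),
            "d": GeneStatusCall("d", "g", "uncertain"),
        }
        states = binarize(calls)
        assert dict(states) == {"a": "1", "b": "0", "c": "0", "d": "?"}

    def test_idempotent_through_reapplication(self):
        calls = {"a": GeneStatusCall("a", "g", "complete"), "b": GeneStatusCall("b", "g", "absent")}
        s1 = binarize(calls)
        # rebuilding call objects from the binarized states and re-binarizing
        # changes nothing
        calls2 = {
            sp: GeneStatusCall(sp, "g", "complete" if v == "1" else "absent")
            for sp, v in s1.items()
        }
        assert dict(binarize(calls2)) == dict(s1)


class TestCountLosses:
    def test_all_present_no_losses(self, quartet):
        assert count_losses(quartet, make_states(quartet, "1111")).n_losses == 0

    def test_two_losses_hand_case(self, quartet):
        report = count_losses(quartet, make_states(quartet, "1000"))
        assert report.n_losses == 2
        assert sorted(map(sorted, report.loss_clades)) == [["B"], ["C", "D"]]

    def test_uncertain_tips_never_force_losses(self, quartet):
        report = count_losses(quartet, make_states(quartet, "1?1?"))
        assert report.n_losses == 0

    def test_uncertain_joins_adjacent_loss_clade(self):
        tree = parse_newick("(((A:1,B:1):1,C:1):1,D:1);")
        report = count_losses(tree, TraitStates({"A": "0", "B": "?", "C": "0", "D": "1"}))
        assert report.n_losses == 1
        assert sorted(report.loss_clades[0]) == ["A", "B", "C"]

    @pytest.mark.parametrize("n_tips", [4, 6, 8, 10])
    def test_matches_brute_force_dollo(self, n_tips, rng):
        for rep in range(5):
            tree = simulate_tree(n_tips, 1.0, seed=500 + 10 * n_tips + rep)
            symbols = rng.choice(["0", "1", "?"], n_tips, p=[0.35, 0.5, 0.15])
            if "1" not in symbols:
                symbols[0] = "1"
            states = make_states(tree, symbols)
            assert count_losses(tree, states).n_losses == brute_force_dollo(tree, states)

    def test_mismatched_species_raise(self, quartet):
        with pytest.raises(KeyError):
            count_losses(quartet, TraitStates({"A": "1"}))


class TestThinTree:
    def test_bifurcating_tree_with_small_clades_unchanged(self, quartet):
        states = make_states(quartet, "1100")
        out = thin_tree(quartet, states)
        assert out.tip_labels == quartet.tip_labels

    def test_four_star_resolved_minimally(self):
        star = parse_newick("(A:1,B:1,C:1,D:1);")
        states = TraitStates({s: "1" for s in "ABCD"})
        out = thin_tree(star, states)
        assert out.is_bifurcating
        # a rooted k-furcation needs k-2 child subtrees removed
        assert out.n_tips == 2

    def test_large_loss_clade_capped_at_three(self):
        tree = parse_newick(
            "(((((L1:1,L2:1):1,(L3:1,L4:2):1):1,L5:4):1,P1:5):1,P2:6);"
        )
        states = TraitStates(
            {"L1": "0", "L2": "0", "L3": "0", "L4": "0", "L5": "0", "P1": "1", "P2": "1"}
        )
        quality = {s: 1.0 for s in states}
        out = thin_tree(tree, states, quality, max_per_loss=3)
        kept_zero = [t for t in out.tip_labels if states[t] == "0"]
        assert len(kept_zero) == 3
        # diversity maximization keeps the deepest-split representatives:
        # L5 plus one from {L1,L2} and the longer of {L3,L4}
        assert "L5" in kept_zero
        assert count_losses(out, states.restrict(set(out.tip_labels))).n_losses == 1

    def test_loss_count_preserved(self):
        tree = parse_newick("((A:1,B:1,C:1):1,(D:1,E:1):1);")
        states = TraitStates({"A": "1", "B": "1", "C": "0", "D": "1", "E": "1"})
        out = thin_tree(tree, states)
        assert out.is_bifurcating
        report = count_losses(out, states.restrict(set(out.tip_labels)))
        assert report.n_losses == 1  # C's loss survives the polytomy fix

    def test_error_when_transition_cannot_be_preserved(self):
        # the only absent species sits in a polytomy whose resolution must
        # keep it; forcing its removal via quality cannot happen -- instead
        # craft a case where every resolution drops the transition
        star = parse_newick("(A:1,B:1,C:1);")
        states = TraitStates({"A": "0", "B": "1", "C": "1"})
        out = thin_tree(star, states)  # keeps A plus one present species
        assert set(out.tip_labels) >= {"A"}
        assert count_losses(out, states.restrict(set(out.tip_labels))).n_losses == 1

    def test_simulated_trees_stay_consistent(self):
        tree = simulate_tree(24, 1.0, seed=77)
        states = simulate_trait(tree, RateSpec2(0.05, 0.15), 1, seed=78)
        before = count_losses(tree, states).n_losses
        out = thin_tree(tree, states, max_per_loss=2)
        after = count_losses(out, states.restrict(set(out.tip_labels))).n_losses
        assert after == before
        assert out.is_bifurcating
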