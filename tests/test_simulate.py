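import numpy as np
import pytest

from coevotrait.codon import CODONS, CodonModelParams
from coevotrait.ctmc import RateSpec2, RateSpec4, transition_matrix
from coevotrait.screen import read_matrix, write_matrix
from coevotrait.simulate import (
    SimulationRecipe,
    make_matrix,
    simulate_codon_alignment,
    simulate_tree,
    simulate_trait,
)


class TestSimulateTree:
    def test_two_tips_is_cherry(self):
        tree = simulate_tree(2, 1.0, seed=0)
        assert tree.n_tips == 2
        depths = tree.depths()
        assert depths["t1"] == pytest.approx(depths["t2"], abs=1e-12)

    @pytest.mark.parametrize("n", [4, 16, 64])
    def test_ultrametric(self, n):
        tree = simulate_tree(n, 1.0, seed=n)
        depths = list(tree.depths().values())
        assert max(depths) - min(depths) < 1e-9
        assert tree.is_bifurcating

    def test_deterministic_given_seed(self):
        assert simulate_tree(12, 1.0, seed=5).to_newick() == simulate_tree(12, 1.0, seed=5).to_newick()
        assert simulate_tree(12, 1.0, seed=5).to_newick() != simulate_tree(12, 1.0, seed=6).to_newick()

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulate_tree(1, 1.0)
        with pytest.raises(ValueError):
            simulate_tree(4, -1.0)


class TestSimulateTrait:
    def test_zero_length_branches_copy_root_state(self):
        from coevotrait.phylo import parse_newick

        tree = parse_newick("((A:0,B:0):0,C:0);")
        states = simulate_trait(tree, RateSpec2(5, 5), 1, seed=1)
        assert set(states.values()) == {"1"}

    def test_stationary_frequency_on_deep_tree(self):
        # rate-5 symmetric chain on depth ~log(16) trees: tips are at
        # stationarity, so state 1 appears half the time
        ones = total = 0
        for rep in range(60):
            tree = simulate_tree(16, 1.0, seed=rep)
            states = simulate_trait(tree, RateSpec2(5, 5), 1, seed=1000 + rep)
            ones += sum(1 for v in states.values() if v == "1")
            total += 16
        assert ones / total == pytest.approx(0.5, abs=0.04)

    def test_single_branch_matches_transition_matrix(self):
        from coevotrait.phylo import parse_newick

        rates = RateSpec2(0.8, 0.3)
        tree = parse_newick("(A:1.0,B:1.0);")
        draws = [
            simulate_trait(tree, rates, 1, seed=s)["A"] == "1" for s in range(4000)
        ]
        expected = transition_matrix(rates, 1.0)[1, 1]
        assert np.mean(draws) == pytest.approx(expected, abs=0.025)

    def test_joint_chain_returns_pair(self):
        tree = simulate_tree(8, 1.0, seed=3)
        focal, gene = simulate_trait(tree, RateSpec4(*([0.5] * 8)), 3, seed=9)
        assert set(focal.species) == set(tree.tip_labels)
        assert set(gene.species) == set(tree.tip_labels)


class TestMakeMatrix:
    def test_round_trips_through_matrix_reader(self, tmp_path):
        tree = simulate_tree(16, 1.0, seed=2)
        rec = SimulationRecipe(seed=2, n_tips=16, n_independent=4, n_coevolving=2)
        matrix, focal, truth, manifest = make_matrix(tree, rec)
        path = tmp_path / "m.tsv"
        write_matrix(matrix, path)
        again = read_matrix(path)
        assert (again.values == matrix.values).all()
        assert manifest["seed"] == 2
        assert sorted(truth) == sorted(matrix.columns)

    def test_pure_null_dataset(self):
        tree = simulate_tree(16, 1.0, seed=4)
        rec = SimulationRecipe(seed=4, n_tips=16, n_independent=5, n_coevolving=0)
        matrix, focal, truth, _ = make_matrix(tree, rec)
        assert set(truth.values()) == {"independent"}
        assert matrix.shape == (16, 5)

    def test_focal_has_multiple_losses(self):
        from coevotrait.gene_status import count_losses

        tree = simulate_tree(64, 1.0, seed=8)
        rec = SimulationRecipe(seed=8)
        _, focal, _, _ = make_matrix(tree, rec)
        assert count_losses(tree, focal).n_losses >= rec.min_focal_losses

    def test_dependent_regime_enriches_joint_absence(self):
        # gene losses should concentrate under focal-absent tips
        both_absent = gene_absent = 0
        for rep in range(12):
            tree = simulate_tree(48, 1.0, seed=300 + rep)
            rec = SimulationRecipe(seed=300 + rep, n_tips=48, n_independent=0, n_coevolving=1)
            matrix, focal, _, _ = make_matrix(tree, rec)
            for sp in matrix.index:
                if matrix.iloc[:, 0][sp] == "0":
                    gene_absent += 1
                    if focal[sp] == "0":
                        both_absent += 1
        assert gene_absent > 0
        assert both_absent / gene_absent > 0.5


class TestSimulateCodonAlignment:
    def test_omega_zero_forbids_amino_acid_change(self):
        from Bio.Data import CodonTable

        tree = simulate_tree(4, 1.0, seed=6)
        params = CodonModelParams(
            kappa=2.0, omega={"all": 0.0}, freqs=np.full(61, 1 / 61), freq_model="equal"
        )
        aln = simulate_codon_alignment(tree, params, 120, seed=6)
        table = CodonTable.unambiguous_dna_by_id[1].forward_table
        proteins = {
            sp: "".join(table[s[i : i + 3]] for i in range(0, len(s), 3))
            for sp, s in aln.sequences.items()
        }
        assert len(set(proteins.values())) == 1

    def test_zero_branch_lengths_give_identical_tips(self):
        from coevotrait.phylo import parse_newick

        tree = parse_newick("((A:0,B:0):0,C:0);")
        params = CodonModelParams(
            kappa=2.0, omega={"all": 1.0}, freqs=np.full(61, 1 / 61), freq_model="equal"
        )
        aln = simulate_codon_alignment(tree, params, 50, seed=1)
        assert len(set(aln.sequences.values())) == 1

    def test_empirical_frequencies_approach_stationary(self):
        tree = simulate_tree(2, 1.0, seed=9)
        freqs = np.full(61, 1 / 61)
        params = CodonModelParams(kappa=2.0, omega={"all": 1.0}, freqs=freqs, freq_model="equal")
        aln = simulate_codon_alignment(tree, params, 6000, seed=9)
        counts = np.zeros(61)
        from coevotrait.codon import CODON_INDEX

        for seq in aln.sequences.values():
            for i in range(0, len(seq), 3):
                counts[CODON_INDEX[seq[i : i + 3]]] += 1
        emp = counts / counts.sum()
        assert np.abs(emp - freqs).max() < 0.01

    def test_invalid_codon_count(self):
        tree = simulate_tree(2, 1.0, seed=1)
        params = CodonModelParams(
            kappa=2.0, omega={"all": 1.0}, freqs=np.full(61, 1 / 61), freq_model="equal"
        )
        with pytest.raises(ValueError):
            simulate_codon_alignment(tree, params, 0, seed=1)


def test_generators_reproducible_bit_for_bit():
    tree1 = simulate_tree(24, 1.0, seed=13)
    tree2 = simulate_tree(24, 1.0, seed=13)
    assert tree1.to_newick() == tree2.to_newick()
    rec = SimulationRecipe(seed=13, n_tips=24, n_independent=3, n_coevolving=2)
    m1, f1, t1, _ = make_matrix(tree1, rec)
    m2, f2, t2, _ = make_matrix(tree2, rec)
    assert (m1.values == m2.values).all()
    assert dict(f1) == dict(f2)
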