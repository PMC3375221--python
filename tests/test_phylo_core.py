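import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from regdiverge import phylo_core as pc
from regdiverge import synthetic_data as sd

from conftest import enumeration_log_likelihood


def random_params(rng):
    pi = rng.dirichlet([10, 10, 10, 10])
    return pc.HKY85Params(float(rng.uniform(0.5, 8.0)), pi)


class TestTransitionProbs:
    def test_zero_branch_is_identity(self, hky_params):
        P = pc.hky85_transition_probs(hky_params, 0.0)
        np.testing.assert_allclose(P, np.eye(4), atol=1e-12)

    def test_long_branch_reaches_stationarity(self):
        params = pc.HKY85Params(2.0, np.full(4, 0.25))
        P = pc.hky85_transition_probs(params, 1e6)
        np.testing.assert_allclose(P, np.tile(params.pi, (4, 1)), atol=1e-8)

    def test_matches_matrix_exponential_oracle(self):
        params = pc.HKY85Params(2.0, np.array([0.3, 0.2, 0.2, 0.3]))
        Q = pc.hky85_rate_matrix(params)
        P = pc.hky85_transition_probs(params, 0.1)
        np.testing.assert_allclose(P, expm(Q * 0.1), atol=1e-8)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_stochasticity_detailed_balance_chapman_kolmogorov(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng)
        s, t = rng.uniform(0.01, 2.0, size=2)
        eig = pc.HKY85EigenSystem(params)
        Ps, Pt, Pst = eig.transition_probs(np.array([s, t, s + t]))
        for P in (Ps, Pt, Pst):
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(P >= -1e-12) and np.all(P <= 1 + 1e-12)
        flux = params.pi[:, None] * Pt
        np.testing.assert_allclose(flux, flux.T, atol=1e-10)
        np.testing.assert_allclose(Ps @ Pt, Pst, atol=1e-8)

    def test_negative_branch_rejected(self, hky_params):
        with pytest.raises(ValueError, match="non-negative"):
            pc.hky85_transition_probs(hky_params, -0.1)

    def test_zero_frequency_rejected(self):
        params = pc.HKY85Params(2.0, np.array([0.5, 0.5, 0.0, 0.0]))
        with pytest.raises(ValueError, match="zero base frequency"):
            pc.hky85_transition_probs(params, 0.1)


class TestPruningLikelihood:
    def test_single_invariant_column_zero_lengths(self, hky_params):
        aln = pc.NucAlignment.from_sequences(
            {"cer": "A", "par": "A", "mik": "A", "bay": "A"}
        )
        tree = pc.yeast_tree(np.zeros(5))
        ll = pc.pruning_log_likelihood(aln, tree, hky_params)
        assert ll == pytest.approx(np.log(hky_params.pi[0]), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng)
        tree = pc.yeast_tree(rng.uniform(0.01, 0.5, size=5))
        ncols = int(rng.integers(1, 7))
        matrix = rng.integers(-1, 4, size=(4, ncols)).astype(np.int8)
        if np.all(matrix < 0):
            matrix[0, 0] = 0
        aln = pc.NucAlignment(("cer", "par", "mik", "bay"), matrix)
        ratios = rng.uniform(0.2, 3.0, size=5)
        ll = pc.pruning_log_likelihood(aln, tree, params, pc.BranchRates.free(ratios))
        oracle = enumeration_log_likelihood(aln, tree, params, ratios)
        assert ll == pytest.approx(oracle, abs=1e-9)

    def test_concatenation_adds(self, hky_params, scaled_tree):
        aln = sd.simulate_alignment(
            scaled_tree, hky_params, pc.BranchRates.shared(1.0), 60, seed=3
        )
        a = aln.take_columns(np.arange(30))
        b = aln.take_columns(np.arange(30, 60))
        whole = pc.pruning_log_likelihood(aln, scaled_tree, hky_params)
        parts = pc.pruning_log_likelihood(a, scaled_tree, hky_params) + \
            pc.pruning_log_likelihood(b, scaled_tree, hky_params)
        assert whole == pytest.approx(parts, abs=1e-9)

    def test_invariant_to_column_and_taxon_order(self, hky_params, scaled_tree):
        aln = sd.simulate_alignment(
            scaled_tree, hky_params, pc.BranchRates.shared(1.0), 40, seed=4
        )
        ll = pc.pruning_log_likelihood(aln, scaled_tree, hky_params)
        shuffled = aln.take_columns(np.random.default_rng(0).permutation(40))
        assert pc.pruning_log_likelihood(shuffled, scaled_tree, hky_params) == \
            pytest.approx(ll, abs=1e-9)
        order = [2, 0, 3, 1]
        relabeled = pc.NucAlignment(
            tuple(aln.taxa[i] for i in order), aln.matrix[order]
        )
        assert pc.pruning_log_likelihood(relabeled, scaled_tree, hky_params) == \
            pytest.approx(ll, abs=1e-9)

    def test_all_gap_column_is_missing_data_not_crash(self, hky_params, scaled_tree):
        base = pc.NucAlignment.from_sequences(
            {"cer": "ACG", "par": "ACG", "mik": "ACG", "bay": "ACG"}
        )
        gapped = pc.NucAlignment.from_sequences(
            {"cer": "ACG-", "par": "ACG-", "mik": "ACG-", "bay": "ACG-"}
        )
        ll_base = pc.pruning_log_likelihood(base, scaled_tree, hky_params)
        ll_gap = pc.pruning_log_likelihood(gapped, scaled_tree, hky_params)
        # an all-missing column contributes likelihood 1 (log 0)
        assert ll_gap == pytest.approx(ll_base, abs=1e-9)

    def test_taxa_mismatch_is_labeled_error(self, hky_params, scaled_tree):
        aln = pc.NucAlignment.from_sequences(
            {"cer": "A", "par": "A", "mik": "A", "wrong": "A"}
        )
        with pytest.raises(ValueError, match="do not match"):
            pc.pruning_log_likelihood(aln, scaled_tree, hky_params)


class TestFourfoldExtraction:
    def test_fourfold_codon_retained(self):
        aln = pc.NucAlignment.from_sequences(
            {t: "GCT" for t in ("cer", "par", "mik", "bay")}
        )
        assert pc.extract_fourfold_sites(aln).length == 1

    def test_twofold_codon_dropped(self):
        aln = pc.NucAlignment.from_sequences(
            {"cer": "TTTGGA", "par": "TTTGGA", "mik": "TTTGGA", "bay": "TTTGGA"}
        )
        sites = pc.extract_fourfold_sites(aln)
        assert sites.length == 1  # GGA (Gly) kept, TTT (Phe) dropped

    def test_mixed_degeneracy_dropped(self):
        aln = pc.NucAlignment.from_sequences(
            {"cer": "GCTGGA", "par": "GCTGGA", "mik": "GCTGGA", "bay": "AATGGA"}
        )
        assert pc.extract_fourfold_sites(aln).length == 1  # only GGA column

    def test_gapped_codon_dropped(self):
        aln = pc.NucAlignment.from_sequences(
            {"cer": "GC-GGA", "par": "GCTGGA", "mik": "GCTGGA", "bay": "GCTGGA"}
        )
        assert pc.extract_fourfold_sites(aln).length == 1

    def test_degeneracy_classes_match_genetic_code_oracle(self):
        from Bio.Data.CodonTable import standard_dna_table

        table = standard_dna_table.forward_table
        fourfold = pc.fourfold_degenerate_codons()
        for codon in fourfold:
            aas = {table.get(codon[:2] + b) for b in "ACGT"}
            assert len(aas) == 1 and None not in aas

    def test_frame_error(self):
        aln = pc.NucAlignment.from_sequences(
            {t: "GCTA" for t in ("cer", "par", "mik", "bay")}
        )
        with pytest.raises(ValueError, match="divisible by 3"):
            pc.extract_fourfold_sites(aln)


class TestBranchLengths:
    def test_identical_sequences_give_zero_lengths(self, scaled_tree):
        matrix = np.tile(np.array([0, 1, 2, 3] * 50, dtype=np.int8), (4, 1))
        aln = pc.NucAlignment(scaled_tree.tip_labels, matrix)
        fit = pc.estimate_branch_lengths(aln, scaled_tree)
        assert fit.tree.branch_lengths.max() < 1e-6

    def test_recovers_simulated_lengths(self, scaled_tree):
        params = pc.HKY85Params(3.0, np.array([0.31, 0.19, 0.17, 0.33]))
        aln = sd.simulate_alignment(
            scaled_tree, params, pc.BranchRates.shared(1.0), 50_000, seed=11
        )
        fit = pc.estimate_branch_lengths(aln, scaled_tree)
        assert fit.converged
        rel_err = np.abs(fit.tree.branch_lengths - scaled_tree.branch_lengths) \
            / scaled_tree.branch_lengths
        assert np.all(rel_err < 0.10)

    def test_variable_column_beats_zero_tree(self, scaled_tree, hky_params):
        invariant = "ACGT" * 5
        rows = {"cer": invariant + "C", "par": invariant + "A",
                "mik": invariant + "A", "bay": invariant + "A"}
        aln = pc.NucAlignment.from_sequences(rows)
        fit = pc.estimate_branch_lengths(aln, scaled_tree, estimate_kappa=False)
        zero = pc.pruning_log_likelihood(
            aln, scaled_tree.with_branch_lengths(np.full(5, 1e-8)),
            pc.HKY85Params(2.0, pc.empirical_base_frequencies(aln)),
        )
        assert fit.log_likelihood > zero

    def test_optimum_beats_grid_probes(self, scaled_tree):
        params = pc.HKY85Params(2.0, np.full(4, 0.25))
        aln = sd.simulate_alignment(
            scaled_tree, params, pc.BranchRates.shared(1.0), 2_000, seed=21
        )
        fit = pc.estimate_branch_lengths(aln, scaled_tree)
        pi = pc.empirical_base_frequencies(aln)
        rng = np.random.default_rng(0)
        for _ in range(10):
            probe = scaled_tree.branch_lengths * rng.uniform(0.3, 3.0, size=5)
            ll = pc.pruning_log_likelihood(
                aln, scaled_tree.with_branch_lengths(probe),
                pc.HKY85Params(fit.kappa, pi),
            )
            assert fit.log_likelihood >= ll - 1e-6


class TestContainers:
    def test_fasta_round_trip(self, tmp_path, scaled_tree, hky_params):
        aln = sd.simulate_alignment(
            scaled_tree, hky_params, pc.BranchRates.shared(1.0), 30, seed=8,
            indel_fraction=0.1,
        )
        path = tmp_path / "aln.fa"
        aln.to_fasta(path)
        back = pc.NucAlignment.from_fasta(path)
        assert back.taxa == aln.taxa
        np.testing.assert_array_equal(back.matrix, aln.matrix)

    def test_newick_round_trip(self, scaled_tree):
        back = pc.ScaledTree.from_newick(scaled_tree.to_newick())
        assert back.branch_names == scaled_tree.branch_names
        np.testing.assert_allclose(back.branch_lengths, scaled_tree.branch_lengths)

    def test_branch_rates_validation(self):
        with pytest.raises(ValueError):
            pc.BranchRates("constrained", np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            pc.BranchRates("unconstrained", np.array([1.0, -2.0]))
        assert pc.BranchRates.free([1, 2, 3, 4, 5]).per_branch(5).size == 5
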