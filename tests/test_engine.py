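"""Coalescent-engine checks against closed-form and brute-force oracles."""

import numpy as np
import pytest

from copulse.engine import (
    Demography,
    FoldedSFS,
    SaturationError,
    expected_sfs,
    fold_spectrum,
    read_dadi_sfs,
    read_sfs,
    simulate_genealogy,
    simulate_sequences,
    simulate_sfs_freq,
    simulate_sfs_freq_batch,
    subtend_probabilities,
    write_sfs,
)

CONST = Demography(100_000, 1.0, 0)


class TestDemography:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            Demography(1, 1.0, 0)
        with pytest.raises(ValueError):
            Demography(100, 0.0, 0)
        with pytest.raises(ValueError):
            Demography(100, -2.0, 0)
        with pytest.raises(ValueError):
            Demography(100, 1.0, -5)

    def test_ancestral_size(self):
        assert Demography(1000, 0.1, 50).n_ancestral == pytest.approx(100.0)


class TestSimulateGenealogy:
    def test_pairwise_mean_total_length_constant_size(self, rng):
        # for n=2 the total length is 2*T_2 with E[T_2] = M generations
        M = 5_000
        d = Demography(M, 1.0, 0)
        totals = [simulate_genealogy(2, d, rng).sum() for _ in range(10_000)]
        mean, se = np.mean(totals), np.std(totals) / np.sqrt(len(totals))
        assert abs(mean - 2 * M) < 3 * se

    def test_epsilon_one_matches_constant_regardless_of_tau(self):
        # identical seeds: epsilon=1 histories are constant size for any tau
        a = simulate_genealogy(8, Demography(1000, 1.0, 0), np.random.default_rng(7))
        b = simulate_genealogy(8, Demography(1000, 1.0, 123_456), np.random.default_rng(7))
        np.testing.assert_allclose(a, b)

    def test_mean_class_profile_is_watterson(self, rng):
        # E[branch length in derived class i] is proportional to 1/i
        d = Demography(2_000, 1.0, 0)
        acc = np.zeros(19)
        reps = 20_000
        for _ in range(reps):
            acc += simulate_genealogy(20, d, rng)
        profile = acc / acc.sum()
        expected = 1.0 / np.arange(1, 20)
        expected /= expected.sum()
        assert np.abs(profile - expected).max() < 0.01

    def test_requires_two_samples(self, rng):
        with pytest.raises(ValueError):
            simulate_genealogy(1, CONST, rng)


class TestSubtendProbabilities:
    def test_rows_are_distributions(self):
        P = subtend_probabilities(20)
        for k in range(2, 21):
            assert P[k].sum() == pytest.approx(1.0)

    def test_level_two_uniform(self):
        # with 2 lineages left, each subtends 1..n-1 leaves uniformly
        P = subtend_probabilities(12)
        np.testing.assert_allclose(P[2], np.full(11, 1 / 11))

    def test_level_n_all_singletons(self):
        P = subtend_probabilities(12)
        assert P[12, 0] == pytest.approx(1.0)


class TestSimulateSfsFreq:
    def test_shape_and_normalisation(self, rng):
        sfs = simulate_sfs_freq(20, 500, Demography(10_000, 0.05, 5_000), rng)
        assert sfs.proportions.shape == (10,)
        assert sfs.proportions.sum() == pytest.approx(1.0)
        assert sfs.n_snps == 500

    def test_converges_to_expected_sfs_constant_size(self, rng):
        sim = simulate_sfs_freq(20, 100_000, CONST, rng)
        exp = expected_sfs(20, CONST)
        assert np.abs(sim.proportions - exp.proportions).max() < 5e-3

    def test_kernel_agrees_with_explicit_topology_mode(self):
        # same distribution via interval-level sampling and via realised trees
        d = Demography(50_000, 0.05, 20_000)
        n_gene = 20_000
        kern = simulate_sfs_freq(20, n_gene, d, np.random.default_rng(1))
        tree = simulate_sfs_freq(20, n_gene, d, np.random.default_rng(2), method="tree")
        se = np.sqrt(kern.proportions * (1 - kern.proportions) / n_gene)
        assert np.all(np.abs(kern.proportions - tree.proportions) < 5 * se + 5e-4)

    def test_batch_rows_sum_to_n_genealogies(self, rng):
        counts = simulate_sfs_freq_batch(
            20, 250, np.array([1e4, 2e4]), np.array([0.1, 1.0]), np.array([5e3, 0.0]), rng
        )
        assert counts.shape == (2, 10)
        np.testing.assert_array_equal(counts.sum(axis=1), [250, 250])

    def test_bit_reproducible_given_seed(self):
        d = Demography(80_000, 0.05, 30_000)
        a = simulate_sfs_freq(20, 2_000, d, np.random.default_rng(42))
        b = simulate_sfs_freq(20, 2_000, d, np.random.default_rng(42))
        np.testing.assert_array_equal(a.proportions, b.proportions)


class TestExpectedSfs:
    def test_branch_share_constant_closed_form(self):
        exp = expected_sfs(20, CONST, estimator="branch-share")
        w = np.array([1 / i + 1 / (20 - i) for i in range(1, 10)] + [1 / 10])
        np.testing.assert_allclose(exp.proportions, w / w.sum())

    def test_epsilon_one_independent_of_tau(self):
        a = expected_sfs(20, Demography(1000, 1.0, 0), estimator="branch-share")
        b = expected_sfs(20, Demography(1000, 1.0, 999), estimator="branch-share")
        np.testing.assert_allclose(a.proportions, b.proportions)

    def test_strong_expansion_shifts_mass_to_singletons(self, rng):
        expanded = expected_sfs(
            20, Demography(100_000, 0.01, 10_000), n_replicates=20_000, rng=rng
        )
        const = expected_sfs(20, CONST)
        assert expanded.proportions[0] > const.proportions[0]

    def test_folding_symmetry_exact(self):
        # folding the unfolded expectation equals the folded closed form
        unfolded = 1.0 / np.arange(1, 20)
        folded = fold_spectrum(unfolded)
        exp = expected_sfs(20, CONST, estimator="branch-share")
        np.testing.assert_allclose(folded / folded.sum(), exp.proportions)


class TestSimulateSequences:
    def test_tiny_mu_limit_gives_no_sites(self, rng):
        block = simulate_sequences(6, 100, 1e-15, CONST, rng)
        assert block.n_sites == 0

    def test_watterson_segregating_sites(self, rng):
        # E[S] = theta * a_{n-1} with theta = 2 N mu L under the engine scaling
        n, L, mu, N = 10, 10_000, 1e-7, 2_000
        d = Demography(N, 1.0, 0)
        reps = 2_000
        s = np.array([simulate_sequences(n, L, mu, d, rng).n_sites for _ in range(reps)])
        a = np.sum(1.0 / np.arange(1, n))
        expected = 2 * N * mu * L * a
        se = s.std() / np.sqrt(reps)
        assert abs(s.mean() - expected) < 4 * se

    def test_every_column_polymorphic(self, rng):
        block = simulate_sequences(8, 5_000, 5e-6, Demography(5_000, 1.0, 0), rng)
        assert block.n_sites > 0
        counts = block.sequences.sum(axis=0)
        assert np.all((counts > 0) & (counts < 8))

    def test_saturation_raises(self, rng):
        with pytest.raises(SaturationError):
            simulate_sequences(10, 3, 1.0, Demography(10_000, 1.0, 0), rng)


class TestSfsIO:
    def test_round_trip(self, tmp_path, rng):
        sfs = simulate_sfs_freq(20, 300, CONST, rng)
        path = tmp_path / "taxon.sfs"
        write_sfs(sfs, path)
        back = read_sfs(path)
        assert back.n_samples == 20 and back.n_snps == 300
        np.testing.assert_allclose(back.proportions, sfs.proportions, atol=1e-6)

    def test_dadi_dialect_import(self, tmp_path):
        # 20 haploid samples -> 21 entries; masked corners
        counts = np.zeros(21)
        counts[1:11] = [50, 20, 10, 5, 5, 4, 3, 1, 1, 1]
        path = tmp_path / "pop.fs"
        path.write_text(
            "21 folded\n"
            + " ".join(str(c) for c in counts)
            + "\n"
            + " ".join(["1"] + ["0"] * 19 + ["1"])
            + "\n"
        )
        sfs = read_dadi_sfs(path)
        assert sfs.n_samples == 20
        assert sfs.n_snps == 100
        assert sfs.proportions[0] == pytest.approx(0.5)

    def test_unfolded_dadi_rejected(self, tmp_path):
        path = tmp_path / "pop.fs"
        path.write_text("21 unfolded\n" + " ".join(["1"] * 21) + "\n")
        with pytest.raises(ValueError):
            read_dadi_sfs(path)
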