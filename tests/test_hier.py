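"""Hyperprior construction, buffered time draws and realised-history checks."""

import numpy as np
import pytest
from scipy import stats

from copulse.hier import (
    BufferInfeasibleError,
    admissible_intervals,
    apply_buffer,
    build_hyperprior,
    draw_codemo,
    draw_event_times,
    draw_taxon_params,
    summarize_params,
)


def _design(**overrides):
    cfg = {
        "n_taxa": 10,
        "scheme": "psi",
        "psi_support": (0, 1, 2, 3),
        "tau_prior": (5_000, 250_000),
        "epsilon_prior": (0.01, 0.10),
        "n_prior": (50_000, 250_000),
        "beta": 0,
    }
    cfg.update(overrides)
    return build_hyperprior(cfg)


class TestBuildHyperprior:
    def test_even_splits_fixed_table(self):
        spec = _design(
            psi_support=(1, 2, 5),
            fixed_zeta={1: (1.0,), 2: (0.5, 0.5), 5: (0.2,) * 5},
        )
        by_psi = {a.psi: a for a in spec.atoms}
        assert by_psi[2].zeta_s == (0.5, 0.5)
        assert by_psi[5].zeta_s == (0.2,) * 5
        assert by_psi[1].zeta_s == (1.0,)

    def test_psi_zero_cell_is_full_idiosyncrasy(self):
        spec = _design(psi_support=(0,))
        (atom,) = spec.atoms
        assert atom.zeta_s == () and atom.zeta_t == 0.0

    def test_crp_enumerates_all_set_partitions(self):
        # 4 taxa -> Bell(4) = 15 equally weighted set partitions
        spec = build_hyperprior({"n_taxa": 4, "scheme": "crp"})
        total = sum(a.weight for a in spec.atoms)
        assert total == pytest.approx(1.0)
        single_pulse = [a for a in spec.atoms if a.zeta_s == (1.0,)]
        assert len(single_pulse) == 1
        assert single_pulse[0].weight == pytest.approx(1 / 15)

    def test_zeta_t_scheme_weights(self):
        spec = build_hyperprior(
            {
                "n_taxa": 10,
                "scheme": "zeta-t",
                "psi_support": (0, 1),
                "zeta_t_grid": (0.2, 0.4, 0.6, 0.8, 1.0),
            }
        )
        w0 = sum(a.weight for a in spec.atoms if a.psi == 0)
        w1 = {a.zeta_t: a.weight for a in spec.atoms if a.psi == 1}
        assert w0 == pytest.approx(0.5)
        assert all(w == pytest.approx(0.1) for w in w1.values())

    def test_empty_admissible_set_rejected(self):
        with pytest.raises(ValueError):
            _design(
                psi_support=(1,),
                zeta_constraints={"min_zeta_t": 0.9, "max_zeta_s": 0.3},
            )

    def test_non_integer_taxon_count_rejected(self):
        with pytest.raises(ValueError):
            _design(psi_support=(1,), fixed_zeta={1: (0.55,)})

    def test_hyperprior_draw_frequencies_match_weights(self):
        spec = _design()
        rng = np.random.default_rng(5)
        draws = [draw_codemo(spec, rng) for _ in range(20_000)]
        observed = np.array(
            [sum(1 for d in draws if d.psi == p) for p in spec.psi_support]
        )
        expected = np.array(
            [sum(a.weight for a in spec.atoms if a.psi == p) for p in spec.psi_support]
        )
        chi2 = stats.chisquare(observed, expected * len(draws))
        assert chi2.pvalue > 1e-4


class TestApplyBuffer:
    def test_worked_example_split_prior(self):
        # placing 100,000 with beta=20,000 leaves U{10000,79999} U U{120001,1000000}
        got = admissible_intervals((10_000, 1_000_000), [100_000], 20_000)
        assert got == [(10_000, 79_999), (120_001, 1_000_000)]

    def test_draws_avoid_the_window(self, rng):
        for _ in range(500):
            t = apply_buffer((10_000, 1_000_000), [100_000], 20_000, rng)
            assert 10_000 <= t <= 1_000_000
            assert not (80_000 <= t <= 120_000)

    def test_beta_zero_excludes_only_drawn_points(self, rng):
        taken = [5, 6, 7, 9]
        for _ in range(200):
            t = apply_buffer((5, 10), taken, 0, rng)
            assert t in (8, 10)

    def test_packing_limit(self, rng):
        # width 245,000 with beta=30,000 admits at most 9 mutually buffered
        # events ((k-1) * beta must stay below the width)
        with pytest.raises(BufferInfeasibleError):
            draw_event_times(10, (5_000, 250_000), 30_000, rng, max_retries=50)
        times = draw_event_times(10, (5_000, 250_000), 10_000, rng)
        gaps = np.diff(np.sort(times))
        assert gaps.min() > 10_000

    def test_empty_set_reports_placed_count(self, rng):
        with pytest.raises(BufferInfeasibleError) as err:
            apply_buffer((0, 10), [5], 100, rng)
        assert err.value.n_placed == 1


class TestDrawCodemo:
    def test_fig_configuration_bookkeeping(self):
        spec = _design(psi_support=(3,), fixed_zeta={3: (0.3, 0.2, 0.3)}, beta=1)
        draw = draw_codemo(spec, np.random.default_rng(0))
        assert draw.zeta_t == pytest.approx(0.8)
        assert draw.S_T == 8
        assert draw.sigma == 2
        assert draw.Psi == 5
        assert sorted(draw.S) == [2, 3, 3]

    def test_full_synchrony(self, rng):
        spec = _design(psi_support=(1,), fixed_zeta={1: (1.0,)})
        draw = draw_codemo(spec, rng)
        params = draw_taxon_params(draw, spec, rng)
        assert draw.Psi == 1 and draw.sigma == 0
        assert len(set(params.tau)) == 1

    def test_psi_zero_all_times_distinct(self, rng):
        spec = _design(psi_support=(0,), beta=500)
        draw = draw_codemo(spec, rng)
        params = draw_taxon_params(draw, spec, rng)
        assert draw.psi == 0 and draw.sigma == 10
        assert len(set(params.tau)) == 10

    def test_invariants_hold_over_many_draws(self):
        rng = np.random.default_rng(99)
        specs = [
            _design(beta=2_000, beta_overrides={0: 1_000}),
            _design(psi_support=(0, 1), scheme="zeta-t",
                    zeta_t_grid=(0.2, 0.4, 0.6, 0.8, 1.0)),
            build_hyperprior({"n_taxa": 6, "scheme": "crp", "beta": 3_000,
                              "tau_prior": (5_000, 250_000)}),
        ]
        for _ in range(10_000):
            spec = specs[rng.integers(len(specs))]
            draw = draw_codemo(spec, rng)
            draw.validate()
            beta = spec.beta_for(draw.psi)
            assert draw.min_event_separation() > beta

    def test_psi_conversion_under_full_assignment(self):
        # zeta_T forced to 1: psi=0 maps to Psi=n, psi=k>0 to Psi=k
        from copulse.pipeline import psi_to_capital

        np.testing.assert_array_equal(
            psi_to_capital(np.array([0, 1, 2, 5]), 10), [10, 1, 2, 5]
        )
        spec = _design(psi_support=(2,), fixed_zeta={2: (0.5, 0.5)})
        draw = draw_codemo(spec, np.random.default_rng(3))
        assert draw.Psi == 2  # sigma = 0, so Psi = psi directly


class TestDrawTaxonParams:
    def test_pulse_members_share_times(self, rng):
        spec = _design(psi_support=(3,), fixed_zeta={3: (0.3, 0.2, 0.3)}, beta=1)
        draw = draw_codemo(spec, rng)
        params = draw_taxon_params(draw, spec, rng)
        for j, (s, t) in enumerate(zip(draw.S, draw.tau_s), start=1):
            members = np.flatnonzero(params.pulse_id == j)
            assert len(members) == s
            assert np.all(params.tau[members] == t)

    def test_nuisance_marginals_uniform(self):
        spec = _design(psi_support=(1,), fixed_zeta={1: (1.0,)})
        rng = np.random.default_rng(11)
        eps, taus, ns = [], [], []
        for _ in range(3_000):
            draw = draw_codemo(spec, rng)
            p = draw_taxon_params(draw, spec, rng)
            eps.extend(p.epsilon[:2])
            ns.extend(p.n_e[:2])
            taus.append(p.tau[0])
        ks_eps = stats.kstest(eps, stats.uniform(0.01, 0.09).cdf)
        assert ks_eps.pvalue > 1e-4
        ks_tau = stats.kstest(taus, stats.uniform(5_000, 245_000).cdf)
        assert ks_tau.pvalue > 1e-4
        ks_n = stats.kstest(ns, stats.uniform(50_000, 200_000).cdf)
        assert ks_n.pvalue > 1e-4

    def test_contraction_partition_uses_reciprocal_prior(self, rng):
        spec = _design(
            psi_support=(1,),
            fixed_zeta={1: (1.0,)},
            scenario_partition=("expansion",) * 5 + ("contraction",) * 5,
        )
        p = draw_taxon_params(draw_codemo(spec, rng), spec, rng)
        assert np.all(p.epsilon[:5] < 1)
        assert np.all(p.epsilon[5:] > 1)
        assert np.all((10 <= p.epsilon[5:]) & (p.epsilon[5:] <= 100))


class TestSummarizeParams:
    def test_zero_dispersion_under_synchrony(self, rng):
        spec = _design(psi_support=(1,), fixed_zeta={1: (1.0,)})
        params = draw_taxon_params(draw_codemo(spec, rng), spec, rng)
        s = summarize_params(params)
        assert s.omega_tau == 0.0

    def test_hand_computed_oracle(self):
        from copulse.hier import TaxonParams

        params = TaxonParams(
            tau=np.array([10_000, 10_000, 40_000]),
            epsilon=np.ones(3),
            n_e=np.ones(3),
            pulse_id=np.arange(3),
        )
        s = summarize_params(params)
        # two-pass: mean 20,000; sample variance 3e8; omega = 15,000
        assert s.e_tau == pytest.approx(20_000)
        assert s.omega_tau == pytest.approx(3e8 / 20_000)

    def test_scaling_homogeneity(self):
        from copulse.hier import TaxonParams

        base = np.array([7.0, 11.0, 23.0, 4.0])
        p1 = TaxonParams(base, np.ones(4), np.ones(4), np.arange(4))
        p2 = TaxonParams(base * 3, np.ones(4), np.ones(4), np.arange(4))
        s1, s2 = summarize_params(p1), summarize_params(p2)
        assert s2.e_tau == pytest.approx(3 * s1.e_tau)
        assert s2.omega_tau == pytest.approx(3 * s1.omega_tau)

    def test_zero_mean_rejected(self):
        from copulse.hier import TaxonParams

        params = TaxonParams(np.zeros(3), np.ones(3), np.ones(3), np.arange(3))
        with pytest.raises(ValueError):
            summarize_params(params)
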