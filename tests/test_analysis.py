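"""Ensemble orchestration, scaling fits, pair scatter and recovery curves."""

import numpy as np
import pytest

import photoepistasis as pe
from photoepistasis.analysis import (
    NoiseFloorError,
    default_trial_schedule,
    exceedance_fraction,
)


def _spectrum_of(coeffs: dict[int, float], n_loci: int) -> pe.WalshSpectrum:
    arr = np.zeros(2**n_loci)
    for mask, c in coeffs.items():
        arr[mask] = c
    return pe.WalshSpectrum(n_loci, arr)


class TestRunEnsemble:
    def test_additive_trait_has_no_epistasis_at_any_eps(self, reference):
        loci = reference.locus_names()[:5]
        summary = pe.run_ensemble(
            reference, loci, (0.01, 0.1, 1.0), n_sets=3,
            evaluator=pe.make_additive_trait(np.arange(1.0, 6.0)),
        )
        assert np.allclose(summary.d_k[:, :, 2:], 0.0, atol=1e-14)
        assert np.all(summary.d_k[:, :, 1] > 0)

    def test_single_replicate_matches_direct_computation(self, reference):
        loci = reference.locus_names()[:4]
        trait = pe.make_interaction_trait((0, 2), 1.5)
        summary = pe.run_ensemble(
            reference, loci, (0.3,), n_sets=1, evaluator=trait, base_seed=5
        )
        assert summary.d_k.shape == (1, 1, 5)
        ps_total = summary.d_k[0, 0] * [1, 4, 6, 4, 1]
        assert ps_total[2] == pytest.approx(1.5**2)

    def test_same_base_seed_reproduces_summary(self, reference):
        loci = reference.locus_names()[:4]
        trait = pe.make_noisy_trait(pe.make_additive_trait([1, 1, 1, 1]), 0.2, seed=0)
        a = pe.run_ensemble(reference, loci, (0.1, 0.3), 2, trait, base_seed=9)
        b = pe.run_ensemble(reference, loci, (0.1, 0.3), 2, trait, base_seed=9)
        assert np.array_equal(a.d_k, b.d_k)
        assert np.array_equal(a.v_epi, b.v_epi)

    def test_trial_schedule_tiers(self):
        sched = default_trial_schedule((0.01, 0.03, 0.1, 0.3, 1.0))
        assert sched[0.01] == sched[0.03] == 5000
        assert sched[0.1] == sched[0.3] == 2000
        assert sched[1.0] == 1000


class TestScalingFits:
    def test_pure_loglinear_gives_exact_slope_two(self, reference):
        loci = reference.locus_names()[:6]
        trait = pe.make_loglinear_trait(
            loci, linear={n: c for n, c in zip(loci, [1, -2, 0.5, 1, 1, 3])}
        )
        summary = pe.run_ensemble(
            reference, loci, (1e-3, 3e-3, 1e-2), n_sets=5,
            evaluator=trait, base_seed=2, shared_xi=True,
        )
        slope, stderr = pe.fit_scaling_exponent(summary, k=1)
        assert slope == pytest.approx(2.0, abs=1e-6)
        assert np.allclose(summary.d_k[:, :, 2:], 0.0, atol=1e-18)

    def test_pair_term_gives_slope_four(self, reference):
        loci = reference.locus_names()[:6]
        trait = pe.make_loglinear_trait(
            loci,
            linear={loci[0]: 1.0, loci[1]: 0.5},
            quadratic={(loci[0], loci[1]): 0.8, (loci[2], loci[3]): -0.6},
        )
        summary = pe.run_ensemble(
            reference, loci, (1e-3, 3e-3, 1e-2), n_sets=5,
            evaluator=trait, base_seed=3, shared_xi=True,
        )
        slope, _ = pe.fit_scaling_exponent(summary, k=2)
        assert slope == pytest.approx(4.0, abs=0.2)

    def test_noise_floor_refusal_names_failing_points(self, reference):
        loci = reference.locus_names()[:4]
        trait = pe.make_additive_trait([1, 1, 1, 1])
        summary = pe.run_ensemble(
            reference, loci, (1e-3, 3e-3, 1e-2), 2, trait, shared_xi=True
        )
        # additive trait: D_2 is identically zero, below any positive floor
        with pytest.raises(NoiseFloorError, match="0.001"):
            pe.fit_scaling_exponent(
                summary, k=2, noise_floor={e: 1e-30 for e in summary.epsilons}
            )

    def test_window_needs_three_points(self, reference):
        loci = reference.locus_names()[:3]
        summary = pe.run_ensemble(
            reference, loci, (1e-3, 1e-2), 2,
            pe.make_additive_trait([1, 1, 1]), shared_xi=True,
        )
        with pytest.raises(ValueError, match="three"):
            pe.fit_scaling_exponent(summary, k=1)


class TestPairScatter:
    def test_single_pair_landscape(self):
        spec = _spectrum_of({0b01: 3.0, 0b10: 4.0, 0b11: 2.0}, 2)
        df = pe.pair_scatter(spec)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["additive_strength"] == pytest.approx(5.0)  # hypot(3,4)
        assert row["epistatic_strength"] == pytest.approx(2.0)
        assert exceedance_fraction(df, threshold=1.0) == 0.0
        assert exceedance_fraction(df, threshold=0.39) == 1.0

    def test_additive_landscape_has_zero_exceedance(self):
        spec = _spectrum_of({0b001: 1.0, 0b010: 0.5, 0b100: 0.2}, 3)
        df = pe.pair_scatter(spec)
        assert np.allclose(df["epistatic_strength"], 0.0)
        assert exceedance_fraction(df) == 0.0

    def test_pure_interaction_pair_exceeds(self):
        spec = _spectrum_of({0b11: 1.0}, 3)
        df = pe.pair_scatter(spec)
        row = df[(df.locus_i == 0) & (df.locus_j == 1)].iloc[0]
        assert row["additive_strength"] == 0.0
        assert row["epistatic_strength"] == 1.0
        assert exceedance_fraction(df) > 0.0

    def test_alternative_comparators(self):
        spec = _spectrum_of({0b01: 3.0, 0b10: 4.0}, 2)
        assert pe.pair_scatter(spec, "sum")["additive_strength"].iloc[0] == 7.0
        assert pe.pair_scatter(spec, "max")["additive_strength"].iloc[0] == 4.0


class TestTopAdditiveRecovery:
    def test_ranking_by_additive_strength(self):
        spec = _spectrum_of({0b01: 1.0, 0b10: 3.0, 0b100: -2.0}, 3)
        np.testing.assert_array_equal(pe.top_additive_subset(spec, 3), [1, 2, 0])
        np.testing.assert_array_equal(pe.top_additive_subset(spec, 1), [1])

    def test_tie_break_by_locus_index(self):
        spec = _spectrum_of({0b01: 1.0, 0b10: -1.0, 0b100: 1.0}, 3)
        np.testing.assert_array_equal(pe.top_additive_subset(spec, 3), [0, 1, 2])

    def test_concentrated_epistasis_recovered_at_m_two(self):
        # interaction lives on the two strongest additive loci
        spec = _spectrum_of({0b01: 3.0, 0b10: 2.0, 0b100: 0.1, 0b11: 1.0}, 3)
        rec = pe.cumulative_variance_curves(spec)
        assert rec.total[1] == pytest.approx(
            (9 + 4 + 1) / (9 + 4 + 0.01 + 1)
        )
        assert rec.total[-1] == pytest.approx(1.0)

    def test_additive_landscape_curves_coincide(self):
        spec = _spectrum_of({0b001: 2.0, 0b010: 1.0, 0b100: 0.5}, 3)
        rec = pe.cumulative_variance_curves(spec)
        np.testing.assert_allclose(rec.additive, rec.additive_plus_pairs)
        np.testing.assert_allclose(rec.additive, rec.total)
        assert rec.total[-1] == pytest.approx(1.0)

    def test_curves_monotone_on_random_spectra(self, rng):
        for _ in range(5):
            values = rng.normal(size=2**6)
            rec = pe.cumulative_variance_curves(pe.walsh_transform(values))
            for curve in (rec.additive, rec.additive_plus_pairs, rec.total):
                assert np.all(np.diff(curve) >= -1e-12)
            assert rec.additive[-1] <= rec.additive_plus_pairs[-1] <= rec.total[-1]
            assert rec.total[-1] == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_rejected(self):
        spec = _spectrum_of({0: 5.0}, 3)
        with pytest.raises(ValueError, match="zero variance"):
            pe.cumulative_variance_curves(spec)


class TestSplitHalfFloor:
    def test_floor_estimates_noise_not_signal(self, reference):
        # two noisy replicates of the same base: floor ~ sigma^2/2^L per order
        L, sigma = 6, 0.3
        loci = reference.locus_names()[:L]
        base = pe.make_additive_trait(np.linspace(1, 0.2, L))
        table = pe.generate_allele_table(reference, loci, 0.5, seed=0)
        land_a = pe.evaluate_trait_landscape(
            table, reference, pe.make_noisy_trait(base, sigma, seed=1), "a"
        )
        land_b = pe.evaluate_trait_landscape(
            table, reference, pe.make_noisy_trait(base, sigma, seed=2), "b"
        )
        floor = pe.split_half_floor(land_a, land_b)
        expected = sigma**2 / 2 / 2**L  # variance of the two-half mean
        assert floor[1:].mean() == pytest.approx(expected, rel=0.5)
        # the floor carries no additive signal: far below the true D_1
        true_d1 = np.mean(np.linspace(1, 0.2, L) ** 2)
        assert floor[1] < 0.05 * true_d1
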