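"""Allele tables, hypercube indexing and landscape evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import photoepistasis as pe
from photoepistasis.kinetics import ConfigurationError


class TestAlleleGeneration:
    def test_zero_epsilon_reproduces_reference(self, reference):
        loci = reference.locus_names()[:5]
        table = pe.generate_allele_table(reference, loci, epsilon=0.0, seed=1)
        for i, name in enumerate(loci):
            assert table.p_minus[i] == pytest.approx(reference[name])
            assert table.p_plus[i] == pytest.approx(reference[name])

    def test_alleles_strictly_positive_at_large_epsilon(self, reference):
        loci = reference.locus_names()
        for seed in range(5):
            table = pe.generate_allele_table(reference, loci, epsilon=2.0, seed=seed)
            assert np.all(table.p_minus > 0) and np.all(table.p_plus > 0)

    def test_fixed_seed_reproduces_table(self, reference):
        loci = reference.locus_names()[:6]
        t1 = pe.generate_allele_table(reference, loci, 0.3, seed=42)
        t2 = pe.generate_allele_table(reference, loci, 0.3, seed=42)
        assert np.array_equal(t1.p_minus, t2.p_minus)
        assert np.array_equal(t1.xi_plus, t2.xi_plus)

    def test_log_ratio_spread_matches_generator(self, reference):
        # std of log(p+/p-) over many draws must be eps*sqrt(2) (independent xi)
        eps, loci = 0.1, reference.locus_names()
        ratios = []
        for seed in range(625):  # 625 tables x 16 loci = 10^4 draws
            t = pe.generate_allele_table(reference, loci, eps, seed=seed)
            ratios.append(np.log(t.p_plus / t.p_minus))
        spread = np.std(np.concatenate(ratios))
        assert spread == pytest.approx(eps * np.sqrt(2), rel=0.03)

    def test_shared_xi_rescaling(self, reference):
        loci = reference.locus_names()[:4]
        base = pe.generate_allele_table(reference, loci, 1.0, seed=9)
        scaled = pe.rescale_allele_table(base, reference, 0.01)
        assert np.array_equal(scaled.xi_plus, base.xi_plus)
        np.testing.assert_allclose(
            np.log(scaled.p_plus / [reference[n] for n in loci]),
            0.01 * base.xi_plus,
        )

    def test_unknown_locus_rejected(self, reference):
        with pytest.raises(ConfigurationError):
            pe.generate_allele_table(reference, ["not_a_rate"], 0.1, seed=0)

    def test_additive_mode_positivity_guard(self, reference):
        loci = reference.locus_names()
        with pytest.raises(ValueError):
            # eps large enough that 1 + eps*xi goes negative for some draw
            for seed in range(50):
                pe.generate_allele_table(reference, loci, 5.0, seed=seed, mode="additive")


class TestHypercubeIndexing:
    @given(st.integers(1, 16), st.data())
    @settings(max_examples=60, deadline=None)
    def test_int_genotype_roundtrip(self, n_loci, data):
        vertex = data.draw(st.integers(0, 2**n_loci - 1))
        s = pe.genotype_from_int(vertex, n_loci)
        assert s.shape == (n_loci,)
        assert set(np.unique(s)) <= {-1, 1}
        assert pe.int_from_genotype(s) == vertex

    def test_bit_zero_is_locus_zero(self):
        s = pe.genotype_from_int(0b001, 3)
        assert s[0] == 1 and s[1] == -1 and s[2] == -1

    def test_flipping_one_locus_changes_one_parameter(self, reference):
        loci = reference.locus_names()[:6]
        table = pe.generate_allele_table(reference, loci, 0.5, seed=2)
        s = pe.genotype_from_int(0b010101, 6)
        p1 = pe.genotype_to_params(table, s, reference)
        s2 = s.copy()
        s2[3] = -s2[3]
        p2 = pe.genotype_to_params(table, s2, reference)
        diffs = [n for n in p1.values if p1[n] != p2[n]]
        assert diffs == [loci[3]]

    def test_extreme_genotypes_pick_pure_allele_sets(self, reference):
        loci = reference.locus_names()[:4]
        table = pe.generate_allele_table(reference, loci, 0.5, seed=3)
        p_minus = pe.genotype_to_params(table, -np.ones(4, dtype=int), reference)
        p_plus = pe.genotype_to_params(table, np.ones(4, dtype=int), reference)
        for i, name in enumerate(loci):
            assert p_minus[name] == table.p_minus[i]
            assert p_plus[name] == table.p_plus[i]
        # non-locus parameters untouched
        assert p_minus["ca_ext"] == reference["ca_ext"]


class TestLandscapeEvaluation:
    def test_identity_readout_reproduces_allele_values(self, reference):
        # trait = value of locus-0 parameter: landscape follows bit 0 only
        loci = reference.locus_names()[:2]
        table = pe.generate_allele_table(reference, loci, 0.7, seed=5)

        def readout(params, s, seed):
            return params[loci[0]], 0.0

        land = pe.evaluate_trait_landscape(table, reference, readout, "p0")
        expected = [table.p_minus[0], table.p_plus[0], table.p_minus[0], table.p_plus[0]]
        np.testing.assert_allclose(land.values, expected)

    def test_constant_trait_gives_flat_landscape(self, reference):
        loci = reference.locus_names()[:3]
        table = pe.generate_allele_table(reference, loci, 0.7, seed=6)
        land = pe.evaluate_trait_landscape(
            table, reference, lambda p, s, seed: (2.5, 0.0), "const"
        )
        assert np.allclose(land.values, 2.5)

    def test_landscape_evaluation_is_deterministic(self, reference):
        loci = reference.locus_names()[:3]
        table = pe.generate_allele_table(reference, loci, 0.4, seed=8)

        def noisy(params, s, seed):
            return float(np.random.default_rng(seed).normal()), 0.0

        a = pe.evaluate_trait_landscape(table, reference, noisy, "x", base_seed=4)
        b = pe.evaluate_trait_landscape(table, reference, noisy, "x", base_seed=4)
        assert np.array_equal(a.values, b.values)

    def test_failed_vertex_blocks_decomposition(self, reference):
        loci = reference.locus_names()[:3]
        table = pe.generate_allele_table(reference, loci, 0.4, seed=8)

        def flaky(params, s, seed):
            if pe.int_from_genotype(s) == 5:
                raise RuntimeError("vertex failed")
            return 1.0, 0.0

        with pytest.raises(RuntimeError, match="5"):
            pe.evaluate_trait_landscape(table, reference, flaky, "x")

    def test_zero_epsilon_landscape_constant_for_deterministic_trait(self, reference):
        loci = reference.locus_names()[:4]
        table = pe.generate_allele_table(reference, loci, 0.0, seed=1)
        trait = pe.make_loglinear_trait(loci, linear={loci[0]: 1.0, loci[2]: 2.0})
        land = pe.evaluate_trait_landscape(table, reference, trait, "ll")
        assert np.ptp(land.values) < 1e-12
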