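"""Hit-integration DP against exact rational integration and quadrature."""

from fractions import Fraction

import numpy as np
import pytest

from seedsense import (
    IntegralTable,
    SimilarityRange,
    exact_hit_polynomial,
    exact_integral,
    gauss_quadrature,
    hit_integration,
    hit_integration_range,
    hit_probability,
    parse_seed,
    reverse_seed,
    similarity_level_free_sensitivity,
)

UPPERS = (0.25, 0.5, 0.75, 1.0)


class TestBaseCases:
    def test_two_consecutive_length_three(self):
        # hit probability is 2p² − p³, whose integral over [0,1] is 5/12
        assert hit_integration(parse_seed("11"), 3, 1.0) == pytest.approx(
            5 / 12, abs=1e-14
        )

    def test_single_window(self):
        # L = m = 2: the only window hits iff both positions match → ∫p² = 1/3
        assert similarity_level_free_sensitivity(
            parse_seed("11"), 2
        ) == pytest.approx(1 / 3, abs=1e-14)

    def test_degenerate_inputs(self):
        seed = parse_seed("1*1")
        assert hit_integration(seed, 10, 0.0) == 0.0
        assert hit_integration(seed, 2, 1.0) == 0.0  # region shorter than seed
        with pytest.raises(ValueError):
            hit_integration(seed, 10, 1.5)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            SimilarityRange(0.7, 0.7)
        with pytest.raises(ValueError):
            SimilarityRange(-0.1, 0.5)
        with pytest.raises(ValueError):
            SimilarityRange(0.5, 1.1)


class TestOracleEquivalence:
    def test_all_small_seeds_exact_rational(self, small_seeds):
        for seed in small_seeds:
            for L in (seed.m, seed.m + 3, 12):
                poly = exact_hit_polynomial(seed, L)
                for p in UPPERS:
                    exact = float(exact_integral(poly, (0.0, p)))
                    assert hit_integration(seed, L, p) == pytest.approx(
                        exact, abs=1e-12
                    )

    @pytest.mark.parametrize("pattern", ["1*11*1*1", "11***1*1", "11111111"])
    def test_length_eight_seeds_at_fourteen(self, pattern):
        seed = parse_seed(pattern)
        poly = exact_hit_polynomial(seed, 14)
        for p in UPPERS:
            exact = float(exact_integral(poly, (0.0, p)))
            assert hit_integration(seed, 14, p) == pytest.approx(exact, abs=1e-12)

    def test_gauss_legendre_exactness(self):
        # the integrand is a degree-≤L polynomial, so ⌈(L+1)/2⌉ nodes suffice
        seed, L = parse_seed("1*1**1"), 12
        rng = SimilarityRange(0.0, 1.0)
        quad = gauss_quadrature(seed, L, rng, nodes=(L + 1 + 1) // 2)
        assert quad == pytest.approx(hit_integration(seed, L, 1.0), abs=1e-12)


class TestRangeAverages:
    def test_full_range_equals_raw_integral(self):
        seed = parse_seed("11*1")
        assert hit_integration_range(
            seed, 10, SimilarityRange(0.0, 1.0)
        ) == pytest.approx(hit_integration(seed, 10, 1.0), abs=1e-15)

    def test_mean_value_bracketed_by_endpoint_probabilities(self):
        # the average of a non-decreasing curve lies between its endpoints
        seed, L = parse_seed("1*1*11"), 20
        rng = SimilarityRange(0.3, 0.8)
        avg = hit_integration_range(seed, L, rng)
        assert hit_probability(seed, L, 0.3) - 1e-12 <= avg
        assert avg <= hit_probability(seed, L, 0.8) + 1e-12

    def test_exact_rational_range(self):
        seed, L = parse_seed("1**1"), 9
        poly = exact_hit_polynomial(seed, L)
        exact = exact_integral(poly, (0.25, 0.75)) / Fraction(1, 2)
        assert hit_integration_range(
            seed, L, SimilarityRange(0.25, 0.75)
        ) == pytest.approx(float(exact), abs=1e-12)

    def test_monotone_in_upper_limit(self):
        seed = parse_seed("11*1")
        vals = [hit_integration(seed, 12, p) for p in np.linspace(0, 1, 9)]
        assert np.all(np.diff(vals) >= 0)

    @pytest.mark.parametrize("pattern", ["11*1", "1*1**1", "1**1*11"])
    def test_reversal_symmetry(self, pattern):
        seed = parse_seed(pattern)
        assert similarity_level_free_sensitivity(
            seed, 16
        ) == pytest.approx(
            similarity_level_free_sensitivity(reverse_seed(seed), 16),
            abs=1e-12,
        )


class TestIntegralTable:
    def test_entries_match_oracle_at_shorter_lengths(self):
        # Iⁿ[i, ε] is ∫₀^p p′ⁿ·f(i, ε) dp′ where f(i, ε) is the length-i curve
        seed, L, p = parse_seed("1*1"), 8, 0.75
        table = IntegralTable.build(seed, L, p)
        for i in (4, 6, 8):
            poly = exact_hit_polynomial(seed, i)
            for n in range(0, L - i + 1):
                shifted = tuple(
                    [Fraction(0)] * n + list(poly.coefficients)
                )
                expected = float(
                    exact_integral(
                        poly.__class__(seed=seed, L=i + n, coefficients=shifted),
                        (0.0, p),
                    )
                )
                assert table.value(n, i, "") == pytest.approx(expected, abs=1e-12)

    def test_degree_band_enforced(self):
        seed = parse_seed("1*1")
        table = IntegralTable.build(seed, 8, 1.0)
        with pytest.raises(ValueError):
            table.value(1, 8, "")  # n_max = L − i + |b| = 0 at the root
        with pytest.raises(ValueError):
            table.value(0, 5, "11")  # n_min = ones in b = 2
        with pytest.raises(KeyError):
            table.value(0, 5, "10")  # incompatible suffix

    def test_bounds_on_entries(self):
        # 0 ≤ Iⁿ[i,b] ≤ ∫₀^p p′ⁿ dp′ = p^(n+1)/(n+1)
        seed, p = parse_seed("11*1"), 0.9
        table = IntegralTable.build(seed, 10, p)
        for n, i, b in [(0, 10, ""), (1, 9, "1"), (2, 6, "11")]:
            v = table.value(n, i, b)
            assert 0.0 <= v <= p ** (n + 1) / (n + 1) + 1e-15
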