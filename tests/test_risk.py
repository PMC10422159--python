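"""ELCR, risk-band classification, and the Monte Carlo engine."""

import dataclasses

import numpy as np
import pytest

from asbestos_risk import (
    ConfigurationError,
    ExposureParameters,
    InputDistribution,
    RiskBands,
    ValidationError,
    classify_risk,
    elcr,
    exposure_concentration,
    monte_carlo_elcr,
)

IUR = 0.23


def point_factors(c):
    p = ExposureParameters()
    return [
        InputDistribution.point("C", c),
        InputDistribution.point("ET", p.exposure_time),
        InputDistribution.point("EF", p.exposure_frequency),
        InputDistribution.point("ED", p.exposure_duration),
    ]


class TestElcr:
    def test_hand_product(self):
        assert elcr(1.0396e-3, IUR) == pytest.approx(2.391e-4, rel=1e-3)

    def test_zero_exposure(self):
        assert elcr(0.0, IUR) == 0.0

    def test_reference_year_2013(self):
        ec = exposure_concentration(0.0021)
        assert elcr(ec, IUR) == pytest.approx(7.76e-5, rel=5e-3)

    def test_negative_ec_rejected(self):
        with pytest.raises(ValidationError):
            elcr(-1e-5, IUR)


class TestClassification:
    @pytest.mark.parametrize(
        "risk,expected",
        [
            (2.41e-4, "considerable"),
            (5e-7, "acceptable"),
            (1e-4, "tolerable"),  # boundary values fall in the middle band
            (1e-6, "tolerable"),
            (5e-5, "tolerable"),
        ],
    )
    def test_banding(self, risk, expected):
        assert classify_risk(risk) == expected

    def test_bands_must_be_ordered(self):
        with pytest.raises(ValidationError):
            RiskBands(acceptable_below=1e-4, considerable_above=1e-6)


class TestMonteCarlo:
    def test_point_distributions_collapse_to_deterministic(self):
        result = monte_carlo_elcr(point_factors(0.0065), ExposureParameters(), IUR)
        expected = elcr(exposure_concentration(0.0065), IUR)
        assert result.mean == expected  # bit-identical, not approximate
        assert result.percentile_95 == expected
        assert result.percentile_5 == expected
        assert result.std == 0.0

    def test_same_seed_is_bit_identical(self):
        dists = [InputDistribution.lognormal("C", 0.0065, 1.5)]
        a = monte_carlo_elcr(dists, ExposureParameters(), IUR, seed=7)
        b = monte_carlo_elcr(dists, ExposureParameters(), IUR, seed=7)
        assert dataclasses.asdict(a) == dataclasses.asdict(b)

    def test_different_seeds_differ(self):
        dists = [InputDistribution.lognormal("C", 0.0065, 1.5)]
        a = monte_carlo_elcr(dists, ExposureParameters(), IUR, seed=7)
        b = monte_carlo_elcr(dists, ExposureParameters(), IUR, seed=8)
        assert a.mean != b.mean

    def test_single_iteration_summaries_equal_the_draw(self):
        dists = [InputDistribution.lognormal("C", 0.0065, 1.5)]
        r = monte_carlo_elcr(dists, ExposureParameters(), IUR, n_iterations=1, seed=3)
        assert r.mean == r.percentile_5 == r.percentile_95
        assert r.std == 0.0

    def test_lognormal_mean_preserved_within_three_se(self):
        dists = [InputDistribution.lognormal("C", 0.0065, 1.5)]
        r = monte_carlo_elcr(dists, ExposureParameters(), IUR, seed=11)
        expected = elcr(exposure_concentration(0.0065), IUR)
        se = r.std / np.sqrt(r.n_iterations)
        assert abs(r.mean - expected) < 3 * se

    def test_p95_exceeds_mean_for_right_skewed_input(self):
        dists = [InputDistribution.lognormal("C", 0.0065, 1.5)]
        r = monte_carlo_elcr(dists, ExposureParameters(), IUR, seed=5)
        assert r.percentile_95 > r.mean > r.percentile_5

    def test_convergence_tightens_with_n(self):
        """|MC mean - deterministic| shrinks as n grows, ~1/sqrt(n)."""
        dists = [InputDistribution.lognormal("C", 0.0065, 1.5)]
        expected = elcr(exposure_concentration(0.0065), IUR)
        errors = {}
        for n in (100, 10_000):
            r = monte_carlo_elcr(dists, ExposureParameters(), IUR, n_iterations=n, seed=19)
            errors[n] = abs(r.mean - expected)
            se = r.std / np.sqrt(n)
            assert errors[n] < 3 * se
        assert errors[10_000] < errors[100]

    def test_missing_concentration_distribution_is_error(self):
        with pytest.raises(ConfigurationError, match="concentration"):
            monte_carlo_elcr([], ExposureParameters(), IUR)

    def test_unknown_factor_is_error(self):
        with pytest.raises(ConfigurationError, match="unknown factor"):
            InputDistribution.point("AT", 1.0)

    def test_duplicate_factor_is_error(self):
        dists = [InputDistribution.point("C", 1.0), InputDistribution.point("C", 2.0)]
        with pytest.raises(ConfigurationError, match="duplicate"):
            monte_carlo_elcr(dists, ExposureParameters(), IUR)

    @pytest.mark.parametrize(
        "family,params",
        [
            ("point", {"value": -1.0}),
            ("lognormal", {"mean": 0.0, "gsd": 1.5}),
            ("lognormal", {"mean": 0.1, "gsd": 0.5}),
            ("uniform", {"low": -0.1, "high": 0.1}),
            ("triangular", {"left": -1.0, "mode": 0.0, "right": 1.0}),
        ],
    )
    def test_invalid_supports_rejected(self, family, params):
        with pytest.raises(ValidationError):
            InputDistribution("C", family, params)

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError, match="family"):
            InputDistribution("C", "beta", {"a": 1, "b": 2})
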