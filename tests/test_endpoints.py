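"""Endpoint models: relative risk, lifetime mortality, mesothelioma incidence."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asbestos_risk import (
    AnnualSeries,
    Bound,
    MesotheliomaCalibration,
    PotencyFactors,
    ValidationError,
    build_annual_summary,
    lifetime_mortality_risk,
    mesothelioma_incidence,
    nicholson_ratio_incidence,
    relative_risk,
)
from asbestos_risk.config import table_replication_potency


class TestRelativeRisk:
    def test_no_exposure_is_baseline(self):
        assert relative_risk(0.0, 0.0030) == 1.0

    def test_stated_lung_potency(self):
        assert relative_risk(0.325, 0.0030) == pytest.approx(1.000975, rel=1e-9)

    def test_replication_potency_matches_published_rr(self):
        # the published RR column is consistent with a 10x potency slope
        assert relative_risk(0.325, 0.030) == pytest.approx(1.009, abs=1e-3)

    def test_negative_exposure_rejected(self):
        with pytest.raises(ValidationError):
            relative_risk(-0.1, 0.003)


class TestLifetimeMortality:
    @pytest.mark.parametrize(
        "c_avg,ur,expected",
        [
            (0.0280, 0.0030, 8.4),  # lung, best estimate
            (0.0060, 0.0032, 1.92),  # mesothelioma, best estimate
            (0.0, 0.011, 0.0),
        ],
    )
    def test_per_100k_values(self, c_avg, ur, expected):
        assert lifetime_mortality_risk(c_avg, ur) == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_unit_risk_rejected(self):
        with pytest.raises(ValidationError):
            lifetime_mortality_risk(0.01, 0.0)


class TestMesotheliomaIncidence:
    @pytest.mark.parametrize(
        "x,km,expected",
        [(0.110, 0.021, 2.31), (0.110, 0.065, 7.15), (0.0, 0.065, 0.0)],
    )
    def test_reporting_scale(self, x, km, expected):
        assert mesothelioma_incidence(x, km) == pytest.approx(expected, abs=1e-9)

    def test_negative_exposure_rejected(self):
        with pytest.raises(ValidationError):
            mesothelioma_incidence(-0.1, 0.021)


class TestNicholsonRatio:
    def test_identity_when_potencies_match(self):
        cal = MesotheliomaCalibration(im_ca=6.80, km_sel=0.021, km_nic=0.021)
        assert nicholson_ratio_incidence(cal) == pytest.approx(6.80)

    def test_hand_ratio(self):
        cal = MesotheliomaCalibration(im_ca=2.0, km_sel=0.065, km_nic=0.021)
        assert nicholson_ratio_incidence(cal) == pytest.approx(6.190, abs=5e-4)

    def test_zero_reference_incidence(self):
        cal = MesotheliomaCalibration(im_ca=0.0, km_sel=0.065, km_nic=0.021)
        assert nicholson_ratio_incidence(cal) == 0.0

    def test_zero_nicholson_potency_rejected(self):
        with pytest.raises(ValidationError):
            MesotheliomaCalibration(im_ca=1.0, km_sel=0.02, km_nic=0.0)


class TestPotencyFactors:
    def test_upper_bound_below_best_estimate_rejected(self):
        with pytest.raises(ValidationError):
            PotencyFactors(kl=Bound(0.011, 0.0030))

    def test_defaults_are_ordered(self, default_potency):
        for b in (default_potency.kl, default_potency.km,
                  default_potency.ur_lung, default_potency.ur_meso):
            assert b.ub >= b.be > 0


class TestBuildAnnualSummary:
    def test_2011_row(self):
        series = AnnualSeries(means={2011: 0.0065})
        (row,) = build_annual_summary(series)
        assert row.cumulative_exposure == pytest.approx(0.3250, abs=1e-12)
        assert row.lung_mortality_be == pytest.approx(8.4, abs=0.05)
        assert row.meso_mortality_be == pytest.approx(8.96, abs=0.05)

    def test_2017_headline_values_exact(self):
        series = AnnualSeries(means={2017: 0.0014})
        (row,) = build_annual_summary(series)
        assert row.lung_mortality_be == pytest.approx(1.8, abs=1e-9)
        assert row.meso_mortality_be == pytest.approx(1.92, abs=1e-9)

    def test_observed_c_avg_overrides_weight(self):
        series = AnnualSeries(means={2011: 0.0065})
        (row,) = build_annual_summary(series, c_avg_observed={2011: 0.0280})
        assert row.c_avg == 0.0280
        assert row.lung_mortality_be == pytest.approx(8.4, abs=1e-9)
        assert row.meso_mortality_be == pytest.approx(8.96, abs=1e-9)

    def test_empty_series_is_error(self):
        with pytest.raises(ValidationError, match="empty"):
            build_annual_summary(AnnualSeries(means={}))

    def test_meso_to_lung_be_ratio_is_exact(self, tehran_series, default_potency):
        """Both mortality risks are Cavg-proportional, so their ratio is UR_meso/UR_lung."""
        for row in build_annual_summary(tehran_series):
            assert row.meso_mortality_be / row.lung_mortality_be == pytest.approx(
                0.0032 / 0.0030, rel=1e-12
            )

    def test_replication_config_pins_published_rr_be(self, tehran_series, lung_ref):
        rows = build_annual_summary(tehran_series, potency=table_replication_potency())
        for row in rows:
            assert row.rr_be == pytest.approx(lung_ref.loc[row.year, "rr_be"], abs=1e-3)

    def test_published_tables_reproduced_from_observed_c_avg(
        self, tehran_series, lung_ref, meso_ref, observed_c_avg
    ):
        """With the published Cavg column supplied as data, the mortality
        columns of both published tables come back at printed precision."""
        rows = build_annual_summary(tehran_series, c_avg_observed=observed_c_avg)
        for row in rows:
            assert row.lung_mortality_be == pytest.approx(
                lung_ref.loc[row.year, "lung_mortality_be"], abs=0.05
            )
            assert row.lung_mortality_ub == pytest.approx(
                lung_ref.loc[row.year, "lung_mortality_ub"], abs=0.05
            )
            assert row.meso_mortality_be == pytest.approx(
                meso_ref.loc[row.year, "meso_mortality_be"], abs=0.05
            )
            # published UB column carries second-decimal rounding noise
            assert row.meso_mortality_ub == pytest.approx(
                meso_ref.loc[row.year, "meso_mortality_ub"], abs=0.1
            )


@settings(derandomize=True, max_examples=50)
@given(
    c=st.floats(min_value=1e-5, max_value=0.1),
    kl_be=st.floats(min_value=1e-4, max_value=0.05),
    kl_spread=st.floats(min_value=1.0, max_value=10.0),
    km_be=st.floats(min_value=1e-3, max_value=0.1),
    km_spread=st.floats(min_value=1.0, max_value=10.0),
    ur_be=st.floats(min_value=1e-4, max_value=0.01),
    ur_spread=st.floats(min_value=1.0, max_value=10.0),
)
def test_upper_bound_outputs_dominate_best_estimates(
    c, kl_be, kl_spread, km_be, km_spread, ur_be, ur_spread
):
    """For any valid potency set with UB >= BE, every UB output >= BE output."""
    potency = PotencyFactors(
        kl=Bound(kl_be, kl_be * kl_spread),
        km=Bound(km_be, km_be * km_spread),
        ur_lung=Bound(ur_be, ur_be * ur_spread),
        ur_meso=Bound(ur_be, ur_be * ur_spread),
    )
    (row,) = build_annual_summary(AnnualSeries(means={2015: c}), potency=potency)
    assert row.rr_ub >= row.rr_be
    assert row.lung_mortality_ub >= row.lung_mortality_be
    assert row.meso_incidence_ub >= row.meso_incidence_be
    assert row.meso_mortality_ub >= row.meso_mortality_be


@settings(derandomize=True, max_examples=50)
@given(
    x=st.floats(min_value=1e-6, max_value=10.0),
    scale=st.floats(min_value=0.01, max_value=100.0),
)
def test_endpoint_linearity_under_rescaling(x, scale):
    """RR-1, mortality, and incidence are homogeneous of degree 1 in dose."""
    assert relative_risk(x * scale, 0.003) - 1 == pytest.approx(
        (relative_risk(x, 0.003) - 1) * scale, rel=1e-9
    )
    assert lifetime_mortality_risk(x * scale, 0.0032) == pytest.approx(
        lifetime_mortality_risk(x, 0.0032) * scale, rel=1e-9
    )
    assert mesothelioma_incidence(x * scale, 0.021) == pytest.approx(
        mesothelioma_incidence(x, 0.021) * scale, rel=1e-9
    )
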