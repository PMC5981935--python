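"""Per-submission cost deltas, the money table, break-even, sensitivity."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from econsult import (
    ActivityTimings,
    CostParameters,
    breakeven_rate,
    savings_per_econsult,
    savings_table,
    sensitivity_sweep,
)
from econsult.economics import DEFAULT_S_GRID

# Published savings grid: (% appointments saved, admin, GP, total) in GBP/submission.
PUBLISHED_SAVINGS = [
    (0.74, -1.0, 2.4, 1.3),
    (0.72, -1.0, 2.0, 1.0),
    (0.70, -1.1, 1.7, 0.7),
    (0.68, -1.1, 1.4, 0.3),
    (0.66, -1.1, 1.1, 0.0),
    (0.64, -1.1, 0.8, -0.3),
    (0.62, -1.1, 0.5, -0.7),
    (0.60, -1.1, 0.1, -1.0),
]


class TestSavingsPerEconsult:
    @pytest.mark.parametrize("s, admin, gp, total", PUBLISHED_SAVINGS)
    def test_reproduces_published_grid(self, expected_default, costs, s, admin, gp, total):
        """All 24 money cells of the published table at 1 dp."""
        b = savings_per_econsult(expected_default, costs, s)
        assert b.rounded(1) == (admin, gp, total)

    def test_no_appointments_avoided_is_pure_cost(self, expected_default, costs):
        """At s=0 the service only adds processing time: both components negative."""
        b = savings_per_econsult(expected_default, costs, 0.0)
        assert b.admin_saving == pytest.approx(-5.67 * 17.82 / 60)
        assert b.gp_saving == pytest.approx(-5.9125 * 95.08 / 60)
        assert b.total_saving < 0

    def test_additivity_at_full_precision(self, expected_default, costs):
        for s in np.linspace(0, 1, 11):
            b = savings_per_econsult(expected_default, costs, s)
            assert b.total_saving == b.admin_saving + b.gp_saving

    @pytest.mark.parametrize("s", [-0.01, 1.01])
    def test_fraction_out_of_range_rejected(self, expected_default, costs, s):
        with pytest.raises(ValueError, match="fraction"):
            savings_per_econsult(expected_default, costs, s)

    def test_doubling_gp_rate_doubles_gp_component_only(self, expected_default, costs):
        doubled = replace(costs, gp_cost_per_hour=2 * costs.gp_cost_per_hour)
        b1 = savings_per_econsult(expected_default, costs, 0.73)
        b2 = savings_per_econsult(expected_default, doubled, 0.73)
        assert b2.gp_saving == pytest.approx(2 * b1.gp_saving)
        assert b2.admin_saving == pytest.approx(b1.admin_saving)

    @given(
        s1=st.floats(min_value=0, max_value=1, allow_nan=False),
        s2=st.floats(min_value=0, max_value=1, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_saved_fraction(self, s1, s2):
        from econsult import CategoryMix, NoteUseModel, derive_per_type_resources, expected_resource

        if abs(s1 - s2) < 1e-9:  # below float resolution of the money scale
            return
        lo, hi = sorted((s1, s2))
        exp = expected_resource(
            derive_per_type_resources(ActivityTimings(), NoteUseModel()), CategoryMix()
        )
        costs = CostParameters()
        b_lo = savings_per_econsult(exp, costs, lo)
        b_hi = savings_per_econsult(exp, costs, hi)
        assert b_hi.admin_saving > b_lo.admin_saving
        assert b_hi.gp_saving > b_lo.gp_saving
        assert b_hi.total_saving > b_lo.total_saving


class TestBreakeven:
    def test_headline_rate_just_over_half(self, expected_default, costs):
        """£0.63 charge at the 73% replacement share needs ~0.54 submissions/patient/yr."""
        b = savings_per_econsult(expected_default, costs, 0.73)
        be = breakeven_rate(b, costs)
        assert be.defined
        assert 0.5 < be.submissions_per_patient_per_year < 0.6
        assert be.submissions_per_patient_per_year == pytest.approx(0.54, abs=0.005)

    def test_consistency_rate_times_saving_equals_charge(self, expected_default, costs):
        for s in np.linspace(0.68, 1.0, 9):
            b = savings_per_econsult(expected_default, costs, s)
            be = breakeven_rate(b, costs)
            assert be.defined
            assert be.submissions_per_patient_per_year * b.total_saving == pytest.approx(
                costs.annual_charge_per_patient, abs=1e-9
            )

    def test_undefined_when_saving_non_positive(self, expected_default, costs):
        b = savings_per_econsult(expected_default, costs, 0.60)
        be = breakeven_rate(b, costs)
        assert not be.defined
        assert be.submissions_per_patient_per_year is None

    def test_free_service_breaks_even_immediately(self, expected_default, costs):
        free = replace(costs, annual_charge_per_patient=0.0)
        b = savings_per_econsult(expected_default, free, 0.73)
        assert breakeven_rate(b, free).submissions_per_patient_per_year == 0.0

    def test_rate_decreases_as_more_appointments_saved(self, expected_default, costs):
        rates = []
        for s in np.linspace(0.68, 1.0, 17):
            be = breakeven_rate(savings_per_econsult(expected_default, costs, s), costs)
            rates.append(be.submissions_per_patient_per_year)
        assert all(a > b for a, b in zip(rates, rates[1:]))


class TestSavingsTable:
    def test_default_grid_is_74_down_to_60(self, expected_default, costs):
        table = savings_table(expected_default, costs)
        assert list(table["appointments_saved_pct"]) == [74, 72, 70, 68, 66, 64, 62, 60]

    def test_single_share_matches_direct_call(self, expected_default, costs):
        table = savings_table(expected_default, costs, [0.73])
        b = savings_per_econsult(expected_default, costs, 0.73)
        assert table.loc[0, "total_saving_gbp"] == pytest.approx(b.total_saving)

    def test_total_is_affine_in_s_with_closed_form_slope(self, expected_default, costs):
        """Slope of total saving vs s is (3*admin_rate + 10*gp_rate)/60 per unit."""
        grid = np.linspace(0, 1, 100)
        table = savings_table(expected_default, costs, list(grid))
        slope_expected = (3 * 17.82 + 10 * 95.08) / 60
        fitted = np.polyfit(grid, table["total_saving_gbp"], 1)
        assert fitted[0] == pytest.approx(slope_expected, abs=1e-9)
        residual = table["total_saving_gbp"] - np.polyval(fitted, grid)
        assert np.abs(residual).max() < 1e-9

    def test_total_saving_crosses_zero_once_between_66_and_68(self, expected_default, costs):
        from scipy.optimize import brentq

        grid = np.linspace(0, 1, 1001)
        totals = np.array(
            [savings_per_econsult(expected_default, costs, s).total_saving for s in grid]
        )
        signs = np.sign(totals)
        crossings = np.nonzero(np.diff(signs) > 0)[0]
        assert len(crossings) == 1
        root = brentq(
            lambda s: savings_per_econsult(expected_default, costs, s).total_saving, 0, 1
        )
        assert 0.66 < root < 0.68

    def test_empty_grid_rejected(self, expected_default, costs):
        with pytest.raises(ValueError):
            savings_table(expected_default, costs, [])


class TestSensitivitySweep:
    def test_zero_perturbation_is_identity(self, timings):
        table = sensitivity_sweep(timings, 0.0)
        assert len(table) == 1
        assert table.loc[0, "delta_gbp"] == 0.0

    def test_both_scaling_variants_reported(self, timings):
        table = sensitivity_sweep(timings, 0.2)
        assert set(table["variant"]) == {"baseline", "econsult_admin_only", "all_admin_tasks"}
        assert len(table) == 5  # baseline + 2 directions x 2 variants

    def test_econsult_side_variant_matches_direct_recomputation(self, timings, costs):
        """Scaling only receive/close-off changes the saving by the admin-time delta."""
        from econsult import CategoryMix, NoteUseModel, derive_per_type_resources, expected_resource

        pert, s = 0.2, 0.73
        table = sensitivity_sweep(timings, pert, s=s)
        row = table[(table["variant"] == "econsult_admin_only") & (table["scale"] > 1)]
        scaled = replace(
            timings,
            receive_econsult=timings.receive_econsult * 1.2,
            close_off_with_contact=timings.close_off_with_contact * 1.2,
            close_off_no_contact=timings.close_off_no_contact * 1.2,
        )
        exp = expected_resource(derive_per_type_resources(scaled, NoteUseModel()), CategoryMix())
        direct = savings_per_econsult(exp, costs, s).total_saving
        assert row["total_saving_gbp"].iloc[0] == pytest.approx(direct, abs=1e-12)
        # delta equals -0.2 * (expected admin minutes) * admin rate / 60
        assert row["delta_gbp"].iloc[0] == pytest.approx(-0.2 * 5.67 * 17.82 / 60, abs=1e-9)

    def test_admin_variation_small_relative_to_gp_component(self, timings, costs, expected_default):
        """±20% on admin timings moves the total by far less than the GP cost term."""
        table = sensitivity_sweep(timings, 0.2, s=0.73)
        gp_component = abs(savings_per_econsult(expected_default, costs, 0.73).gp_saving)
        assert table["delta_gbp"].abs().max() < 0.35 * gp_component

    @pytest.mark.parametrize("bad", [-1.0, 1.0, -2.0])
    def test_perturbation_domain(self, timings, bad):
        with pytest.raises(ValueError):
            sensitivity_sweep(timings, bad)


def test_negative_cost_parameter_rejected():
    with pytest.raises(ValueError, match="gp_cost_per_hour"):
        CostParameters(gp_cost_per_hour=-1)
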