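"""Reduced-order detachment model: outcomes, thresholds, calibration,
and the drag/adhesion scaling quantity."""

import math

import numpy as np
import pytest

from emboclot.embolization import (
    AdhesionModel,
    EmbolizationCriterion,
    ThresholdBracket,
    bracket_threshold,
    calibrate_adhesion,
    scaling_quantity,
    simulate_embolization,
    threshold_table,
)
from emboclot.pipeflow import flow_condition

FLOW_42 = flow_condition(4.2)


@pytest.fixture(scope="module")
def contact_area(reference_clot):
    return reference_clot.contact_area()


@pytest.fixture(scope="module")
def F_42(drag_power_law):
    return float(drag_power_law.predict(4.2))


class TestSimulation:
    def test_zero_drag_never_embolizes(self, reference_clot, reference_params,
                                       calibrated_adhesion, criterion,
                                       contact_area):
        out = simulate_embolization(
            FLOW_42, reference_clot, reference_params,
            calibrated_adhesion.with_epsilon_wall(100.0), criterion, 0.0,
            contact_area=contact_area,
        )
        assert not out.embolized
        assert out.max_displacement_fraction == pytest.approx(0.0, abs=1e-12)
        assert out.n_broken[-1] == 0

    def test_far_supercritical_run_detaches_at_leading_edge(
        self, reference_clot, reference_params, calibrated_adhesion, criterion,
        contact_area, F_42,
    ):
        """Well above threshold the first broken bond is the leading-edge
        station and the run embolizes within the window."""
        out = simulate_embolization(
            FLOW_42, reference_clot, reference_params,
            calibrated_adhesion.with_epsilon_wall(50.0), criterion, F_42,
            contact_area=contact_area,
        )
        assert out.embolized
        assert out.first_broken_station == 0
        assert out.t_detach_over_T < criterion.observation_window

    def test_subcritical_run_satisfies_criterion_soundness(
        self, reference_clot, reference_params, calibrated_adhesion, criterion,
        contact_area, F_42,
    ):
        """A run flagged non-embolizing must keep the stored leading-edge
        displacement below 5% of the clot length for the whole window."""
        out = simulate_embolization(
            FLOW_42, reference_clot, reference_params,
            calibrated_adhesion.with_epsilon_wall(1.0), criterion, F_42,
            contact_area=contact_area,
        )
        assert not out.embolized
        assert out.times[-1] >= criterion.observation_window * FLOW_42.timescale
        assert out.max_displacement_fraction < criterion.displacement_fraction

    def test_time_step_self_convergence(self, reference_clot, reference_params,
                                        calibrated_adhesion, criterion,
                                        contact_area, F_42):
        adh = calibrated_adhesion.with_epsilon_wall(1.0)
        d = []
        for frac in (200.0, 400.0):
            out = simulate_embolization(
                FLOW_42, reference_clot, reference_params, adh, criterion, F_42,
                dt=FLOW_42.timescale / frac, contact_area=contact_area,
            )
            d.append(out.leading_edge_displacement[-1])
        assert abs(d[0] / d[1] - 1.0) < 0.02

    def test_coarse_time_step_rejected(self, reference_clot, reference_params,
                                       calibrated_adhesion, criterion, F_42):
        with pytest.raises(ValueError, match="too coarse"):
            simulate_embolization(
                FLOW_42, reference_clot, reference_params,
                calibrated_adhesion.with_epsilon_wall(1.0), criterion, F_42,
                dt=FLOW_42.timescale,
            )

    def test_negative_drag_rejected(self, reference_clot, reference_params,
                                    calibrated_adhesion, criterion):
        with pytest.raises(ValueError):
            simulate_embolization(
                FLOW_42, reference_clot, reference_params,
                calibrated_adhesion.with_epsilon_wall(1.0), criterion, -1.0,
            )


class TestAdhesionModel:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"epsilon_wall": 1.0, "n_stations": 4},
            {"epsilon_wall": -1.0},
            {"epsilon_wall": 1.0, "leading_edge_load_fraction": 1.5},
            {"epsilon_wall": 1.0, "failure_cap": 0.9},
        ],
    )
    def test_invalid_models_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AdhesionModel(**kwargs)

    def test_criterion_validation(self):
        with pytest.raises(ValueError):
            EmbolizationCriterion(displacement_fraction=0.0)


class TestThresholdBracket:
    @pytest.mark.parametrize(
        "lo, hi, expected",
        [(3.0, 5.0, math.sqrt(15.0)), (12.0, 15.0, math.sqrt(180.0))],
    )
    def test_geometric_mean(self, lo, hi, expected):
        assert ThresholdBracket(lo, hi).geometric_mean == pytest.approx(expected)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            ThresholdBracket(5.0, 3.0)


class TestBracketing:
    def test_endpoints_already_within_tolerance(self, reference_clot,
                                                reference_params,
                                                calibrated_adhesion, criterion,
                                                F_42):
        """A bracket whose verified endpoints already satisfy the ratio
        tolerance is returned unchanged."""
        br = bracket_threshold(
            FLOW_42, reference_clot, reference_params, calibrated_adhesion,
            criterion, F_42, eps_lo=4.0, eps_hi=5.0, ratio_tol=1.3,
        )
        assert (br.eps_no, br.eps_yes) == (4.0, 5.0)

    def test_bisection_tightens_to_ratio(self, reference_clot, reference_params,
                                         calibrated_adhesion, criterion, F_42):
        br = bracket_threshold(
            FLOW_42, reference_clot, reference_params, calibrated_adhesion,
            criterion, F_42, eps_lo=0.5, eps_hi=50.0, ratio_tol=1.3,
        )
        assert br.ratio <= 1.3
        assert br.eps_no < br.geometric_mean < br.eps_yes

    def test_endpoints_expanded_when_invalid(self, reference_clot,
                                             reference_params,
                                             calibrated_adhesion, criterion,
                                             F_42):
        """Starting from two embolizing endpoints, the lower endpoint is
        expanded downward until it stops embolizing."""
        br = bracket_threshold(
            FLOW_42, reference_clot, reference_params, calibrated_adhesion,
            criterion, F_42, eps_lo=20.0, eps_hi=50.0, ratio_tol=1.5,
        )
        assert br.eps_no < 20.0
        assert br.ratio <= 1.5


class TestCalibration:
    def test_calibrated_threshold_inside_reference_bracket(
        self, reference_clot, reference_params, calibrated_adhesion, criterion,
        contact_area, F_42,
    ):
        """eps_w = 3 must not embolize and eps_w = 5 must, at 4.2 LPM."""
        lo = simulate_embolization(
            FLOW_42, reference_clot, reference_params,
            calibrated_adhesion.with_epsilon_wall(3.0), criterion, F_42,
            contact_area=contact_area, record=False,
        )
        hi = simulate_embolization(
            FLOW_42, reference_clot, reference_params,
            calibrated_adhesion.with_epsilon_wall(5.0), criterion, F_42,
            contact_area=contact_area, record=False,
        )
        assert not lo.embolized
        assert hi.embolized

    def test_calibration_is_deterministic(self, reference_clot, reference_params,
                                          criterion, drag_power_law,
                                          calibrated_adhesion):
        again, diag = calibrate_adhesion(
            reference_clot, reference_params, criterion, drag_power_law.predict
        )
        assert again == calibrated_adhesion
        assert diag["failure_cap"] == calibrated_adhesion.failure_cap


class TestSweep:
    def test_single_crossing_in_epsilon_wall(self, reference_clot,
                                             reference_params,
                                             calibrated_adhesion, criterion,
                                             contact_area, F_42):
        """Outcome over a 12-point log grid of eps_w shows exactly one
        no -> yes transition."""
        outcomes = []
        for eps in np.geomspace(0.5, 50.0, 12):
            out = simulate_embolization(
                FLOW_42, reference_clot, reference_params,
                calibrated_adhesion.with_epsilon_wall(float(eps)), criterion,
                F_42, contact_area=contact_area, record=False,
            )
            outcomes.append(out.embolized)
        flips = sum(
            1 for a, b in zip(outcomes[:-1], outcomes[1:]) if a != b
        )
        assert flips == 1
        assert not outcomes[0] and outcomes[-1]

    def test_thresholds_and_scaling_across_flow_rates(
        self, reference_clot, reference_params, calibrated_adhesion, criterion,
        drag_power_law, contact_area,
    ):
        """Threshold eps_wt decreases with flow rate and the scaling
        quantity Pi = eps_wt*lambda*F_D/(eta_p*A_c) stays within one
        order of magnitude of 1e-2 at all five flow conditions."""
        table = threshold_table(
            [1.9, 2.8, 4.2, 6.3, 10.0], reference_clot, reference_params,
            calibrated_adhesion, criterion, drag_power_law.predict,
        )
        geomeans = table["eps_geomean"].to_numpy()
        assert np.all(np.diff(geomeans) < 0)
        assert np.all((table["Pi"] >= 0.003) & (table["Pi"] <= 0.03))
        # the 4.2-LPM threshold sits inside the reference bracket
        row = table[table["Q_LPM"] == 4.2].iloc[0]
        assert 3.0 <= row["eps_geomean"] <= 5.0


class TestScalingQuantity:
    def test_zero_drag(self, reference_params):
        assert scaling_quantity(1.0, reference_params, 0.0, 1e-4) == 0.0

    def test_linearity(self, reference_params):
        base = scaling_quantity(2.0, reference_params, 1e-3, 1e-4)
        assert scaling_quantity(4.0, reference_params, 1e-3, 1e-4) == pytest.approx(
            2 * base
        )
        assert scaling_quantity(2.0, reference_params, 2e-3, 1e-4) == pytest.approx(
            2 * base
        )

    def test_reference_magnitude(self, reference_params, contact_area):
        """With the reported 4.2-LPM bracket geometric mean and drag, Pi
        lands at the expected order of magnitude ~1e-2."""
        pi = scaling_quantity(
            math.sqrt(15.0), reference_params, 1.52e-3, contact_area
        )
        assert 0.003 <= pi <= 0.03

    def test_zero_contact_area_rejected(self, reference_params):
        with pytest.raises(ValueError):
            scaling_quantity(1.0, reference_params, 1.0, 0.0)
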