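"""ROI construction, constrained fits, grid search and orchestration."""

import numpy as np
import pytest

import _oracle
from dlmokit import core, segmentation as sg, synthetic
from dlmokit.errors import (
    DegenerateRoiError,
    NoAscendingError,
    ProfileValidationError,
)
from dlmokit.profile import MelatoninProfile


def make(times, concs, id="p"):
    return MelatoninProfile(
        id=id, times=np.asarray(times, float), concentrations=np.asarray(concs, float)
    )


class TestRoi:
    def test_no_intermediate_uses_last_half_of_final_base_segment(self):
        p = make([20.0, 20.5, 21.0, 21.5], [1.0, 1.0, 4.0, 8.0])
        lab = sg.label_segments(p, 2.3)
        roi = core.compute_roi(p, lab, 2.3)
        assert roi.t_lo == 20.25
        assert roi.t_hi == pytest.approx(20.975, abs=1e-12)
        assert (roi.y_lo, roi.y_hi) == (1.0, 2.3)

    def test_intermediate_starts_just_after_last_base_node(self):
        p = make([20.0, 20.5, 21.0, 21.5, 22.0], [1.0, 0.8, 1.2, 3.0, 6.0])
        lab = sg.label_segments(p, 2.3)
        roi = core.compute_roi(p, lab, 2.3)
        assert roi.t_lo == pytest.approx(20.5 + 1e-9, abs=1e-15)
        assert roi.t_hi == pytest.approx(21.475, abs=1e-12)
        assert roi.y_lo == 0.8

    def test_single_base_node_uses_ascending_left_node(self):
        p = make([20.0, 21.0, 22.0], [1.0, 4.0, 8.0])
        lab = sg.label_segments(p, 2.3)
        roi = core.compute_roi(p, lab, 2.3)
        assert roi.t_lo == 20.0
        assert roi.t_hi == pytest.approx(20.95, abs=1e-12)

    def test_no_ascending_raises(self):
        p = make([20.0, 20.5, 21.0, 21.5], [1.0, 1.0, 4.0, 8.0])
        lab = sg.label_segments(p, 2.3)
        for i, l in enumerate(lab.labels):
            if l == "ascending":
                lab.labels[i] = "excluded"
        with pytest.raises(DegenerateRoiError):
            core.compute_roi(p, lab, 2.3)


class TestEarlyFit:
    def test_exact_flat_fit_has_zero_norm(self):
        slope, norm, clamped = core.fit_linear_early(
            [(-2.0, 1.0), (-1.0, 1.0)], (0.0, 1.0)
        )
        assert (slope, norm, clamped) == (0.0, 0.0, False)

    def test_slope_clamped_to_limit_with_frozen_norm(self):
        # unconstrained through-POI slope is 0.5; clamped to 0.2
        slope, norm, clamped = core.fit_linear_early(
            [(-2.0, 0.0), (-1.0, 0.5)], (0.0, 1.0)
        )
        assert slope == 0.2
        assert norm == pytest.approx(0.6708203932499369, abs=1e-12)
        assert clamped

    def test_clamped_norm_matches_brute_force_slope_scan(self):
        pts = np.array([(-2.0, 0.0), (-1.0, 0.5)])
        best = min(
            float(np.linalg.norm(pts[:, 1] - (1.0 + m * pts[:, 0])))
            for m in np.arange(-0.2, 0.2 + 1e-12, 1e-4)
        )
        _, norm, _ = core.fit_linear_early(pts, (0.0, 1.0))
        assert norm == pytest.approx(best, abs=1e-6)

    def test_domain_band_clamp_applies_after_slope_limit(self):
        # unconstrained slope 0.144 is inside +-0.2 but the line would fall
        # below the domain minimum at the left edge; band clamps it to 0.12
        slope, _, clamped = core.fit_linear_early(
            [(-10.0, 1.0), (-5.0, 1.0)], (0.0, 2.2)
        )
        assert slope == pytest.approx(0.12, abs=1e-12)
        assert clamped

    def test_empty_early_set_returns_zero(self):
        slope, norm, _ = core.fit_linear_early(np.empty((0, 2)), (0.0, 1.0))
        assert (slope, norm) == (0.0, 0.0)


class TestLateFits:
    def test_exact_line_through_poi(self):
        pts = [(1.0, 5.0), (2.0, 9.0)]
        slope, norm = core.fit_linear_late(pts, (0.0, 1.0))
        assert slope == pytest.approx(4.0, abs=1e-12)
        assert norm == pytest.approx(0.0, abs=1e-12)

    def test_single_late_point_interpolated_exactly(self):
        slope, norm = core.fit_linear_late([(1.0, 3.5)], (0.0, 1.0))
        assert slope == pytest.approx(2.5, abs=1e-12)
        assert norm == 0.0

    def test_residuals_orthogonal_to_design(self):
        pts = np.array([(1.0, 5.0), (3.0, 4.0)])
        slope, norm = core.fit_linear_late(pts, (0.0, 0.0))
        r = pts[:, 1] - slope * pts[:, 0]
        assert float(np.dot(r, pts[:, 0])) == pytest.approx(0.0, abs=1e-9)
        assert norm == pytest.approx(float(np.linalg.norm(r)), abs=1e-9)

    def test_parabola_recovers_exact_member(self):
        d = np.array([0.5, 1.0, 1.5, 2.0])
        pts = np.column_stack([d, 1.0 + d * d + 4.0 * d])
        a, b, norm = core.fit_parabola_late(pts, (0.0, 1.0), 4.0, 0.0)
        assert a == pytest.approx(1.0, abs=1e-9)
        assert b == pytest.approx(4.0, abs=1e-9)
        assert norm == pytest.approx(0.0, abs=1e-9)

    def test_slope_bound_binds_exactly_when_unconstrained_below_it(self):
        # data on a slope-1 line but coarse slope 4 forces b >= 2
        d = np.array([0.5, 1.0, 1.5, 2.0])
        pts = np.column_stack([d, 1.0 + d])
        a, b, norm = core.fit_parabola_late(pts, (0.0, 1.0), 4.0, 0.0)
        assert b == 2.0
        # projection optimality: no feasible neighborhood point is better
        grid = [
            float(np.linalg.norm(pts[:, 1] - (1.0 + aa * d * d + bb * d)))
            for aa in np.linspace(a - 0.05, a + 0.05, 41)
            for bb in np.linspace(2.0, 2.1, 41)
            if 2 * aa * d.max() + bb >= 1e-6
        ]
        assert norm <= min(grid) + 1e-9

    def test_line_is_admissible_parabola_when_constraints_allow(self):
        d = np.array([0.5, 1.0, 2.0])
        pts = np.column_stack([d, 1.0 + 4.0 * d])
        a, b, norm = core.fit_parabola_late(pts, (0.0, 1.0), 4.0, 0.0)
        assert a == pytest.approx(0.0, abs=1e-9)
        assert b == pytest.approx(4.0, abs=1e-9)

    def test_derivative_stays_positive_over_late_domain(self):
        # hump data whose unconstrained parabola would descend at the end
        d = np.array([0.5, 1.0, 1.5, 2.0])
        pts = np.column_stack([d, 1.0 + np.array([2.0, 3.0, 3.2, 3.1])])
        a, b, _ = core.fit_parabola_late(pts, (0.0, 1.0), 2.0, 0.0)
        assert 2 * a * d.max() + b >= 1e-6 - 1e-9

    def test_parabola_matches_active_set_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            d = np.sort(rng.uniform(0.1, 3.0, 5))
            yv = rng.uniform(0.0, 8.0, 5)
            pts = np.column_stack([d, yv])
            cs = float(rng.uniform(-1, 6))
            es = float(rng.uniform(-0.2, 0.2))
            a, b, norm = core.fit_parabola_late(pts, (0.0, 0.0), cs, es)
            oa, ob, onorm = _oracle.late_parabola(d, yv, 0.0, 0.0, cs, es)
            assert norm == pytest.approx(onorm, abs=1e-9)


class TestPoiCost:
    def test_zero_cost_at_exact_breakpoint(self, clean_profile):
        lab = sg.label_segments(clean_profile, 2.3)
        fit = core.poi_cost(clean_profile, lab, (22.25, 1.0), "coarse")
        assert fit.cost == pytest.approx(0.0, abs=1e-12)

    def test_displaced_poi_costs_more(self, clean_profile):
        lab = sg.label_segments(clean_profile, 2.3)
        fit = core.poi_cost(clean_profile, lab, (22.25, 1.5), "coarse")
        assert fit.cost > 0.1

    def test_cost_is_sum_of_the_two_norms(self, noisy_truth):
        lab = sg.label_segments(noisy_truth.profile, 2.3)
        for phase in ("coarse", "refine"):
            fit = core.poi_cost(noisy_truth.profile, lab, (22.05, 1.2), phase)
            assert fit.cost == fit.early_norm + fit.late_norm

    def test_node_at_poi_time_joins_both_fit_sets(self):
        # three points; POI at the middle point's exact time
        p = make([20.0, 21.0, 22.0, 23.0], [1.0, 1.0, 4.0, 7.0])
        lab = sg.label_segments(p, 2.3)
        fit = core.poi_cost(p, lab, (21.0, 1.0), "coarse")
        # late fit sees (21,1),(22,4),(23,7): exact slope-3 line -> and the
        # early fit sees (20,1),(21,1): exact flat line -> total cost 0
        assert fit.cost == pytest.approx(0.0, abs=1e-12)


class TestGrid:
    def test_axis_counts_span_not_divisible_by_step(self):
        assert len(core._axis(0.0, 0.97, 0.1)) == 10

    def test_axis_includes_on_step_endpoint(self):
        assert len(core._axis(0.0, 1.0, 0.1)) == 11
        assert core._axis(0.0, 1.0, 0.1)[-1] == pytest.approx(1.0, abs=1e-12)

    def test_axis_tolerates_near_step_endpoint_within_1e9(self):
        assert len(core._axis(0.0, 1.0 - 1e-12, 0.1)) == 11

    def test_equal_cost_ties_break_to_earliest_time_lowest_level(self):
        # every POI on the line y = 1 + 0.1 t fits exactly (slope inside the
        # clamp), so many grid points tie at zero cost
        t = np.arange(0.0, 24.0, 4.0)
        p = make(t, 1.0 + 0.1 * t)
        res = core.estimate_dlmo(p, threshold=1.5)
        assert res.dlmo_hours == res.roi.t_lo == 0.0
        assert res.dlmo_conc == 1.0

    def test_refinement_grid_inside_coarse_decile_box(self, noisy_truth):
        res = core.estimate_dlmo(noisy_truth.profile)
        bt_lo, bt_hi, by_lo, by_hi = res.coarse.top_fraction_box
        assert res.refine.t.min() >= bt_lo - 1e-12
        assert res.refine.t.max() <= bt_hi + 1e-12
        assert res.refine.y.min() >= by_lo - 1e-12
        assert res.refine.y.max() <= by_hi + 1e-12

    def test_refinement_never_worsens(self):
        for i in range(8):
            tr = synthetic.generate_profile(onset=21.8 + 0.05 * i, conc_cv=0.079, seed=i)
            res = core.estimate_dlmo(tr.profile)
            assert res.refine.argmin.cost <= res.coarse.argmin.cost + 1e-12

    def test_argmin_is_global_grid_minimum(self, noisy_truth):
        res = core.estimate_dlmo(noisy_truth.profile)
        for grid in (res.coarse, res.refine):
            assert grid.argmin.cost == pytest.approx(float(grid.cost.min()), abs=1e-12)


class TestEstimate:
    def test_recovers_canonical_onset_exactly(self, clean_truth):
        res = core.estimate_dlmo(clean_truth.profile)
        assert res.dlmo_hours == 22.25
        assert res.dlmo_clock == "22:15"
        assert res.dlmo_conc == 1.0
        assert res.best.cost <= 1e-9

    def test_dlmo_lies_inside_roi(self, noisy_truth):
        res = core.estimate_dlmo(noisy_truth.profile)
        assert res.roi.t_lo <= res.dlmo_hours <= res.roi.t_hi
        assert res.roi.y_lo <= res.dlmo_conc <= res.roi.y_hi

    def test_coarse_only_skips_refinement(self, clean_profile):
        res = core.estimate_dlmo(clean_profile, coarse_only=True)
        assert res.refine is None
        assert res.dlmo_hours == res.coarse.argmin.pt

    def test_refine_late_fit_is_parabola_coarse_is_line(self, noisy_truth):
        res = core.estimate_dlmo(noisy_truth.profile)
        assert res.coarse.argmin.late_kind == "linear"
        assert res.refine.argmin.late_kind == "parabola"

    def test_no_dynamic_part_raises_structured_error(self):
        with pytest.raises(ProfileValidationError) as err:
            core.estimate_dlmo(synthetic.degenerate_fixture("all_sub_threshold"))
        assert err.value.status == "no_dynamic_part"

    def test_insufficient_points_raises_structured_error(self):
        with pytest.raises(ProfileValidationError) as err:
            core.estimate_dlmo(synthetic.degenerate_fixture("two_points"))
        assert err.value.status == "insufficient_points"

    def test_all_supra_threshold_has_no_ascending_crossing(self):
        with pytest.raises(NoAscendingError):
            core.estimate_dlmo(synthetic.degenerate_fixture("all_supra_threshold"))

    def test_spurious_spike_locks_onto_later_steady_rise(self):
        res = core.estimate_dlmo(synthetic.degenerate_fixture("spurious_spike"))
        assert res.dlmo_hours >= 21.5  # well after the 20.5 spike

    def test_double_rise_uses_the_later_rise(self):
        res = core.estimate_dlmo(synthetic.degenerate_fixture("double_rise"))
        assert res.dlmo_hours >= 21.5  # after the first rise's down-crossing

    def test_trailing_subthreshold_tail_trimmed_then_estimated(self):
        res = core.estimate_dlmo(synthetic.degenerate_fixture("trailing_subthreshold"))
        assert res.validation.n_trimmed_terminal == 2
        assert res.dlmo_hours == pytest.approx(20.5, abs=1e-9)

    def test_params_echo_round_trips_inputs(self, clean_profile):
        res = core.estimate_dlmo(clean_profile, threshold=2.0, coarse_only=True)
        assert res.params_echo["threshold"] == 2.0
        assert res.params_echo["coarse_only"] is True

    def test_gently_convex_rise_biases_late_never_early(self):
        # the coarse phase fits a line to the convex rise, and the refine
        # parabola's slope floor is half that line's slope: both push the
        # breakpoint late for convex rises, never early
        for i in range(5):
            tr = synthetic.generate_profile(
                onset=21.3 + 0.1 * i, rate=4.0, rise_kind="parabolic",
                quad=0.3, conc_cv=0.0,
            )
            res = core.estimate_dlmo(tr.profile)
            assert tr.true_onset - 0.02 <= res.dlmo_hours <= tr.true_onset + 0.1
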