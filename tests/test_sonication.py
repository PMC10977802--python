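"""Presets, raster planning, and the multi-point treatment simulator."""

import dataclasses
import itertools

import numpy as np
import pytest

from hifusim.bioheat import StabilityError
from hifusim.phantom import Ellipsoid
from hifusim.compare import single_point_plan
from hifusim.sonication import (
    EmptyPlanError,
    SonicationParameters,
    TreatmentPlan,
    plan_grid,
    preset,
    simulate_treatment,
)


class TestPresets:
    def test_group_a_is_the_fibroid_parameter_set(self):
        p = preset("A")
        assert (
            p.point_interval_mm,
            p.focal_intensity_kw_cm2,
            p.duty_cycle_pct,
            p.center_frequency_mhz,
            p.pulse_repetition_hz,
            p.per_point_time_s,
            p.transition_time_s,
        ) == (4.0, 0.8, 60.0, 1.0, 10.0, 6.0, 3.0)

    def test_group_b_is_the_optimized_parameter_set(self):
        p = preset("B")
        assert (
            p.point_interval_mm,
            p.focal_intensity_kw_cm2,
            p.duty_cycle_pct,
            p.center_frequency_mhz,
            p.pulse_repetition_hz,
            p.per_point_time_s,
            p.transition_time_s,
        ) == (2.0, 1.0, 70.0, 1.0, 10.0, 7.0, 3.0)

    def test_unknown_preset_lists_valid_labels(self):
        with pytest.raises(ValueError, match="'A', 'B'"):
            preset("C")

    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            SonicationParameters(4.0, 0.8, 0.0, 1.0, 10.0, 6.0, 3.0)
        with pytest.raises(ValueError):
            SonicationParameters(4.0, 0.8, 120.0, 1.0, 10.0, 6.0, 3.0)


def brute_force_lattice(lesion, spacing, deep_margin):
    """Independent enumeration: every lattice point in the ellipsoid minus
    the deep slab, rastered shallow-first with boustrophedon rows."""
    c = np.asarray(lesion.center_mm)
    s = np.asarray(lesion.semi_axes_mm)
    n = int(np.ceil(max(s) / spacing)) + 1
    pts = []
    for k, j, i in itertools.product(range(-n, n + 1), repeat=3):
        p = c + spacing * np.array([i, j, k])
        if np.sum(((p - c) / s) ** 2) > 1.0 + 1e-12:
            continue
        if p[2] > c[2] + s[2] - deep_margin + 1e-12:
            continue
        pts.append(p)
    planes = {}
    for p in pts:
        planes.setdefault(round(p[2], 9), []).append(p)
    ordered = []
    for z in sorted(planes):
        rows = {}
        for p in planes[z]:
            rows.setdefault(round(p[1], 9), []).append(p)
        for ridx, y in enumerate(sorted(rows)):
            row = sorted(rows[y], key=lambda p: p[0])
            ordered.extend(row if ridx % 2 == 0 else row[::-1])
    return np.array(ordered)


class TestPlanGrid:
    def test_matches_brute_force_enumeration(self):
        lesion = Ellipsoid((0.0, 0.0, 0.0), (10.0, 10.0, 10.0))
        plan = plan_grid(lesion, preset("A"), deep_margin_mm=4.0)
        oracle = brute_force_lattice(lesion, 4.0, 4.0)
        assert plan.n_points == len(oracle)
        assert np.allclose(plan.points_mm, oracle)

    def test_halved_spacing_multiplies_count_by_eight(self):
        lesion = Ellipsoid((0.0, 0.0, 0.0), (20.0, 20.0, 20.0))
        n4 = plan_grid(lesion, preset("A")).n_points
        n2 = plan_grid(lesion, preset("B")).n_points
        assert 8.0 * 0.75 <= n2 / n4 <= 8.0 * 1.25

    def test_deep_margin_excludes_deepest_centimeter(self):
        lesion = Ellipsoid((0.0, 0.0, 0.0), (20.0, 20.0, 20.0))
        plan = plan_grid(lesion, preset("A"), deep_margin_mm=10.0)
        deepest_allowed = 20.0 - 10.0
        assert plan.points_mm[:, 2].max() <= deepest_allowed + 1e-12

    def test_lesion_thinner_than_margin_is_empty(self):
        lesion = Ellipsoid((0.0, 0.0, 0.0), (8.0, 8.0, 4.0))
        with pytest.raises(EmptyPlanError):
            plan_grid(lesion, preset("A"), deep_margin_mm=10.0)

    def test_plan_points_inside_lesion_invariant(self):
        lesion = Ellipsoid((0.0, 0.0, 0.0), (12.0, 9.0, 11.0))
        plan = plan_grid(lesion, preset("B"))
        assert np.all(lesion.contains(plan.points_mm))

    def test_point_outside_lesion_rejected(self):
        lesion = Ellipsoid((0.0, 0.0, 0.0), (5.0, 5.0, 15.0))
        with pytest.raises(ValueError, match="inside the lesion"):
            TreatmentPlan(points_mm=np.array([[10.0, 0.0, 0.0]]), lesion=lesion)


class TestSimulateTreatment:
    def test_protocol_timing_arithmetic(self, small_phantom, small_template):
        """10 points with preset B: 10·7 + 9·3 = 97 s total, 10·7·0.7 = 49 s on."""
        lesion = small_phantom.lesion
        # 10 points all at the center are legal for timing purposes
        plan = TreatmentPlan(
            points_mm=np.zeros((10, 3)), lesion=lesion, deep_margin_mm=0.0
        )
        res = simulate_treatment(
            plan, preset("B"), small_phantom, template=small_template, dt_s=0.25
        )
        assert res.duration_s == pytest.approx(97.0, abs=1e-12)
        assert res.on_time_s == pytest.approx(49.0, abs=1e-12)

    def test_negligible_intensity_produces_no_lesion(
        self, small_phantom, small_template
    ):
        params = dataclasses.replace(preset("B"), focal_intensity_kw_cm2=1e-9)
        res = simulate_treatment(
            single_point_plan(small_phantom), params, small_phantom,
            template=small_template,
        )
        assert res.ablated_volume_cm3 == 0.0
        assert res.peak_cem43_min < 1.0

    def test_longer_per_point_time_increases_peak_dose(
        self, small_phantom, small_template
    ):
        muscle = small_phantom.with_uniform_perfusion(0.7)
        short = simulate_treatment(
            single_point_plan(muscle), preset("A"), muscle,
            template=small_template,
        )
        long_params = dataclasses.replace(preset("A"), per_point_time_s=12.0)
        long = simulate_treatment(
            single_point_plan(muscle), long_params, muscle,
            template=small_template,
        )
        assert long.peak_cem43_min > short.peak_cem43_min

    def test_repeated_runs_bit_identical(self, small_phantom, small_template):
        plan = single_point_plan(small_phantom)
        r1 = simulate_treatment(plan, preset("B"), small_phantom,
                                template=small_template)
        r2 = simulate_treatment(plan, preset("B"), small_phantom,
                                template=small_template)
        assert np.array_equal(r1.dose_cem43, r2.dose_cem43)
        assert np.array_equal(r1.peak_temperature_c, r2.peak_temperature_c)
        assert r1.ablated_volume_cm3 == r2.ablated_volume_cm3

    def test_pulsed_and_averaged_duty_agree_on_ablation(
        self, small_phantom, small_template
    ):
        """Explicit 10 Hz gating vs duty-averaged heating: the 100 ms pulse
        period is far below thermal time constants, so the ablated region
        is the same to a few percent (pointwise dose at the very focal peak
        is more sensitive — the dose rate is exponential in T)."""
        plan = single_point_plan(small_phantom)
        avg = simulate_treatment(plan, preset("B"), small_phantom,
                                 template=small_template, dt_s=0.01)
        pul = simulate_treatment(plan, preset("B"), small_phantom,
                                 template=small_template, dt_s=0.01,
                                 duty_mode="pulsed")
        assert pul.ablated_volume_cm3 == pytest.approx(
            avg.ablated_volume_cm3, rel=0.05
        )

    def test_pulsed_mode_requires_dt_resolving_prf(
        self, small_phantom, small_template
    ):
        with pytest.raises(StabilityError, match="pulsing"):
            simulate_treatment(
                single_point_plan(small_phantom), preset("B"), small_phantom,
                template=small_template, dt_s=0.05, duty_mode="pulsed",
            )

    def test_unstable_dt_refused(self, small_phantom, small_template):
        with pytest.raises(StabilityError, match="use dt"):
            simulate_treatment(
                single_point_plan(small_phantom), preset("B"), small_phantom,
                template=small_template, dt_s=5.0,
            )
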