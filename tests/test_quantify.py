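"""Quantification procedures: profiles, ratios, tracks, angles, comets."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import spindlebridge as sb
from spindlebridge.quantify import (
    BackgroundError,
    DegenerateFitError,
    IntensityProfile,
    KinetochoreTrack,
    QuantifyError,
    angle_from_contour,
    bridge_fraction,
    comet_rate,
    dbk_from_profiles,
    estimate_bridge_mt_number,
    interkinetochore_distance,
    kk_relaxation,
    peak_area,
    perpendicular_displacement,
    sister_tilt,
    stub_length,
    subtract_background,
)


def gaussian_profile(center=0.0, area=1.0, sigma=0.15, background=0.0,
                     span=4.0, step=0.081):
    pos = np.arange(-span / 2, span / 2 + step / 2, step)
    inten = background + area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
        -0.5 * ((pos - center) / sigma) ** 2
    )
    return IntensityProfile(position_um=pos, intensity=inten)


class TestBackground:
    def test_flat_profile_minus_its_level_is_zero(self):
        prof = IntensityProfile(np.linspace(0, 2, 30), np.full(30, 10.0))
        out = subtract_background(prof, background=10.0)
        assert np.allclose(out.intensity, 0.0)

    def test_offset_gaussian_recovers_pure_peak(self):
        prof = gaussian_profile(background=5.0)
        pure = gaussian_profile(background=0.0)
        out = subtract_background(prof, background=5.0)
        assert np.allclose(out.intensity, pure.intensity)

    def test_flank_estimate_removes_cytoplasmic_level(self):
        rng = np.random.default_rng(0)
        prof = gaussian_profile(background=100.0)
        noisy = IntensityProfile(
            prof.position_um, prof.intensity + rng.normal(0, 2.0, prof.position_um.size)
        )
        out = subtract_background(noisy, flank_um=0.5)
        pos = out.position_um
        flank = (pos <= pos[0] + 0.5) | (pos >= pos[-1] - 0.5)
        assert abs(np.mean(out.intensity[flank])) < 2.0 / math.sqrt(flank.sum()) * 3

    def test_missing_background_demands_flank(self):
        prof = gaussian_profile()
        with pytest.raises(BackgroundError):
            subtract_background(prof)

    def test_non_monotone_positions_rejected(self):
        with pytest.raises(QuantifyError):
            IntensityProfile(np.array([0.0, 1.0, 0.5]), np.zeros(3))


class TestPeakArea:
    def test_unit_gaussian_wide_window(self):
        prof = gaussian_profile(area=1.0, sigma=0.15)
        area = peak_area(prof, window_width_um=3.0, window_center_um=0.0)
        assert area == pytest.approx(1.0, rel=1e-3)

    def test_all_zero_profile_is_zero(self):
        prof = IntensityProfile(np.linspace(-2, 2, 50), np.zeros(50))
        assert peak_area(prof, window_width_um=1.0) == 0.0

    def test_window_beyond_span_rejected(self):
        prof = gaussian_profile(span=1.0)
        with pytest.raises(QuantifyError):
            peak_area(prof, window_width_um=5.0, window_center_um=0.0)

    def test_area_scales_linearly_with_amplitude(self):
        a1 = peak_area(gaussian_profile(area=1.0), 0.6, window_center_um=0.0)
        a3 = peak_area(gaussian_profile(area=3.0), 0.6, window_center_um=0.0)
        assert a3 == pytest.approx(3 * a1, rel=1e-9)


class TestMtCounts:
    @pytest.mark.parametrize("r,expected", [(0.45, 0.45 / 0.55), (0.0, 0.0),
                                            (0.5, 1.0)])
    def test_bridge_fraction_examples(self, r, expected):
        assert bridge_fraction(r) == pytest.approx(expected, rel=1e-12)

    def test_invalid_ratio_rejected(self):
        for r in (1.0, 1.2, -0.1):
            with pytest.raises(QuantifyError):
                bridge_fraction(r)

    @pytest.mark.parametrize("r,nk,expected", [(0.45, 17, 14), (0.20, 24, 6),
                                               (0.5, 10, 10)])
    def test_mt_number_examples(self, r, nk, expected):
        assert estimate_bridge_mt_number(r, nk) == expected

    @given(r=st.floats(0, 0.95), delta=st.floats(0.001, 0.04))
    @settings(max_examples=100, deadline=None)
    def test_mt_number_monotone_in_ratio(self, r, delta):
        assert estimate_bridge_mt_number(r + delta, 17) >= estimate_bridge_mt_number(r, 17)

    @given(f=st.floats(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_fraction_inverts_to_ratio(self, f):
        """r = f/(1+f) then bridge_fraction(r) = f, to machine precision."""
        r = f / (1 + f)
        assert bridge_fraction(r) == pytest.approx(f, rel=1e-9, abs=1e-12)


class TestContourAngle:
    def test_points_on_axis_have_zero_angle(self):
        pts = np.array([[0, 0], [1, 0], [2, 0]])
        assert angle_from_contour(pts) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_line_is_45_degrees(self):
        pts = np.array([[0, 0], [1, 1], [2, 2]])
        assert angle_from_contour(pts) == pytest.approx(45.0, abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateFitError):
            angle_from_contour(np.zeros((3, 2)))

    def test_noisy_line_recovered_unbiased(self):
        """3-point fits of a 65.5-degree line with 50-nm noise recover the
        angle without bias (mean over replicates within its standard error)."""
        rng = np.random.default_rng(3)
        truth = 65.5
        d = np.array([math.cos(math.radians(truth)), math.sin(math.radians(truth))])
        base = np.outer([0.0, 0.25, 0.5], d)
        est = []
        for _ in range(300):
            pts = base + rng.normal(0, 0.05, (3, 2))
            est.append(angle_from_contour(pts))
        se = np.std(est, ddof=1) / math.sqrt(len(est))
        assert np.mean(est) == pytest.approx(truth, abs=4 * se + 0.3)


def make_track(p1, p2, tip=None, times=None, axis=((0.0, 0.0), (1.0, 0.0)),
               t_cut=0.0):
    times = np.asarray(times if times is not None else [-4.0, 0.0, 4.0, 8.0])
    objs = {
        "sister1": np.column_stack([times, np.tile(p1, (times.size, 1))]),
        "sister2": np.column_stack([times, np.tile(p2, (times.size, 1))]),
    }
    if tip is not None:
        objs["stub_tip"] = np.column_stack([times, np.tile(tip, (times.size, 1))])
    return KinetochoreTrack(objects=objs, axis_origin=axis[0],
                            axis_direction=axis[1], t_cut_s=t_cut)


class TestTracks:
    def test_axis_parallel_sisters_have_zero_tilt(self):
        tr = make_track([0, 1], [1, 1])
        assert sister_tilt(tr, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_perpendicular_sisters_have_right_angle_tilt(self):
        tr = make_track([0, 0], [0, 1])
        assert sister_tilt(tr, 0.0) == pytest.approx(90.0, abs=1e-12)

    def test_coincident_sisters_rejected(self):
        tr = make_track([0, 0], [0, 0])
        with pytest.raises(QuantifyError):
            sister_tilt(tr, 0.0)

    def test_static_sisters_show_no_relaxation(self):
        tr = make_track([0, 1], [1, 1])
        assert kk_relaxation(tr) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_leaves_measures_invariant(self):
        """Tilt, distance and relaxation are invariant when track and axis
        are rotated and translated together."""
        rng = np.random.default_rng(5)
        times = np.array([-4.0, 0.0, 4.0])
        p1 = np.column_stack([times, rng.normal(0, 1, 3), rng.normal(0, 1, 3)])
        p2 = p1 + np.array([0.0, 1.1, 0.4])
        tr = KinetochoreTrack({"sister1": p1, "sister2": p2})
        phi = 0.7
        R = np.array([[math.cos(phi), -math.sin(phi)],
                      [math.sin(phi), math.cos(phi)]])
        shift = np.array([3.0, -2.0])

        def xf(arr):
            out = arr.copy()
            out[:, 1:3] = arr[:, 1:3] @ R.T + shift
            return out

        tr2 = KinetochoreTrack(
            {"sister1": xf(p1), "sister2": xf(p2)},
            axis_origin=tuple(shift), axis_direction=tuple(R @ [1.0, 0.0]),
        )
        for t in times:
            assert sister_tilt(tr2, t) == pytest.approx(sister_tilt(tr, t), abs=1e-9)
            assert interkinetochore_distance(tr2, t) == pytest.approx(
                interkinetochore_distance(tr, t), abs=1e-9
            )
        assert kk_relaxation(tr2) == pytest.approx(kk_relaxation(tr), abs=1e-9)

    def test_no_movement_gives_zero_displacement(self):
        tr = make_track([0, 1], [1, 1])
        assert perpendicular_displacement(tr, "sister1", 4.0) == pytest.approx(0.0)

    def test_axis_parallel_motion_gives_zero_displacement(self):
        times = np.array([0.0, 4.0])
        p1 = np.array([[0.0, 0.0, 1.0], [4.0, 2.0, 1.0]])
        p2 = p1 + np.array([0, 1, 0])
        tr = KinetochoreTrack({"sister1": p1, "sister2": p2})
        assert perpendicular_displacement(tr, "sister1", 4.0) == pytest.approx(0.0)

    def test_outward_motion_is_positive(self):
        times = np.array([0.0, 4.0])
        p1 = np.array([[0.0, 0.0, 1.0], [4.0, 0.0, 1.3]])
        p2 = p1 + np.array([0, 1, 0])
        tr = KinetochoreTrack({"sister1": p1, "sister2": p2})
        assert perpendicular_displacement(tr, "sister1", 4.0) == pytest.approx(0.3)

    def test_stub_length_examples(self):
        tr = make_track([0, 1], [1, 1], tip=[0, 1])
        assert stub_length(tr, 4.0) == pytest.approx(0.0, abs=1e-12)
        tr = make_track([0, 1], [1, 1], tip=[-1, 1])
        assert stub_length(tr, 4.0) == pytest.approx(1.0, abs=1e-12)

    def test_missing_stub_tip_rejected(self):
        tr = make_track([0, 1], [1, 1])
        with pytest.raises(QuantifyError):
            stub_length(tr, 4.0)

    def test_frame_matching_tolerance(self):
        tr = make_track([0, 1], [1, 1], times=[-4.0, 0.0, 3.7, 7.7])
        # 4 s after the cut matched to the 3.7 s frame (within one interval)
        assert interkinetochore_distance(tr, 4.0) == pytest.approx(1.0)
        with pytest.raises(QuantifyError):
            tr.position("sister1", 30.0)


class TestDbk:
    def test_identical_peaks_give_zero(self):
        b = gaussian_profile(center=0.2)
        k = gaussian_profile(center=0.2)
        assert dbk_from_profiles(b, k) == pytest.approx(0.0, abs=1e-9)

    def test_programmed_offset_recovered_and_sign_flips(self):
        b, k = sb.generate_dbk_profiles(
            sb.ProfileParams(noise_sd=0.0), dbk_um=0.24, seed=0
        )
        d = dbk_from_profiles(b, k)
        assert d == pytest.approx(0.24, abs=0.082)  # sampling resolution
        assert dbk_from_profiles(k, b) == pytest.approx(-d, abs=1e-9)


class TestCometRate:
    def test_zero_events(self):
        assert comet_rate([], 10.0) == {}
        assert comet_rate(0, 10.0) == 0.0

    def test_rate_arithmetic(self):
        assert comet_rate(19, 10.0) == pytest.approx(1.9)
        df = pd.DataFrame({"direction": ["toward"] * 19 + ["away"] * 6})
        rates = comet_rate(df, 10.0)
        assert rates["toward"] == pytest.approx(1.9)
        assert rates["away"] == pytest.approx(0.6)

    def test_invalid_duration_rejected(self):
        with pytest.raises(QuantifyError):
            comet_rate(3, 0.0)
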