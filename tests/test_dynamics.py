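import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import filodyn as fd
from filodyn.dynamics import (
    ExtentSeries,
    TrapezoidModel,
    TriangleModel,
    classify_dynamics,
    compute_extent_series,
    fit_trapezoid,
    fit_triangle,
    model_curve,
    summarize_filopodium,
)
from filodyn.errors import NoExtensionError
from filodyn.track_io import pair_frames

from conftest import make_series, make_track


def series_from_coords(base_xy, tip_xy, meta, frames=None):
    track = make_track(base_xy, tip_xy, frames=frames)
    return compute_extent_series(pair_frames(track), meta)


class TestExtentSeries:
    def test_three_four_five(self, meta):
        s = series_from_coords([(0, 0)] * 2, [(3, 4)] * 2, meta)
        assert s.extents == pytest.approx([5.0, 5.0])

    def test_zero_when_base_equals_tip(self, meta):
        s = series_from_coords([(1, 2)] * 3, [(1, 2)] * 3, meta)
        assert np.all(s.extents == 0)

    def test_window_flags(self, meta):
        s = series_from_coords(
            [(0, 0)] * 3, [(1, 0)] * 3, meta, frames=[1, 2, 3]
        )
        assert s.touches_window_start and not s.touches_window_end
        s = series_from_coords(
            [(0, 0)] * 3, [(1, 0)] * 3, meta, frames=[14, 15, 16]
        )
        assert not s.touches_window_start and s.touches_window_end

    coords = st.tuples(
        st.floats(-30, 30, allow_nan=False), st.floats(-30, 30, allow_nan=False)
    )

    @given(
        pts=st.lists(st.tuples(coords, coords), min_size=2, max_size=10),
        shift=coords,
        angle=st.floats(0, 2 * math.pi),
    )
    @settings(max_examples=100, deadline=None)
    def test_rigid_motion_invariance(self, pts, shift, angle):
        meta = fd.AcquisitionMeta()
        base = [p[0] for p in pts]
        tip = [p[1] for p in pts]
        s0 = series_from_coords(base, tip, meta)
        c, sn = math.cos(angle), math.sin(angle)

        def move(p):
            x, y = p
            return (c * x - sn * y + shift[0], sn * x + c * y + shift[1])

        s1 = series_from_coords([move(p) for p in base], [move(p) for p in tip], meta)
        np.testing.assert_allclose(s1.extents, s0.extents, atol=1e-9)
        assert np.all(s1.extents >= 0)


class TestFitTriangle:
    def test_basic_example(self):
        tri = fit_triangle(make_series([2, 4, 2]))
        assert tri.t_origin == -2 and tri.t_end == 6
        assert tri.Emax == 4
        assert tri.Ve == pytest.approx(1.0)
        assert tri.Vr == pytest.approx(1.0)
        assert tri.lifetime == 8.0

    def test_single_frame_spike(self):
        tri = fit_triangle(ExtentSeries(times=[0.0], extents=[5.0], frame_interval=2.0))
        assert tri.Ve == pytest.approx(2.5)
        assert tri.Vr == pytest.approx(2.5)
        assert tri.lifetime == 4.0

    def test_plateau_tie_rule(self):
        tri = fit_triangle(make_series([3, 3]))
        assert tri.t_peak_first == 0 and tri.t_peak_last == 2
        assert tri.Ve == pytest.approx(1.5)
        assert tri.Vr == pytest.approx(1.5)
        assert tri.lifetime == 6.0

    def test_all_zero_raises(self):
        with pytest.raises(NoExtensionError, match="no extension"):
            fit_triangle(make_series([0, 0, 0]))


class TestFitTrapezoid:
    def test_basic_example(self):
        trap = fit_trapezoid(make_series([3, 6, 6, 6, 3]))
        assert trap.t_origin == -2 and trap.t_end == 10
        assert trap.t_half == 4.0
        assert trap.Es == pytest.approx(6.0)
        assert (trap.t_s_start, trap.t_s_end) == (2.0, 6.0)
        assert trap.Vs == 0.0
        assert trap.Ve == pytest.approx(1.5)
        assert trap.Vr == pytest.approx(1.5)
        assert trap.lifetime == 12.0

    def test_triangular_series_degenerates(self):
        trap = fit_trapezoid(make_series([2, 4, 2]))
        tri = fit_triangle(make_series([2, 4, 2]))
        assert trap.t_s_start == trap.t_s_end
        assert trap.Vs == 0.0
        assert trap.Ve == pytest.approx(tri.Ve)
        assert trap.Vr == pytest.approx(tri.Vr)

    @pytest.mark.parametrize("extents", [[1, 3, 5, 3, 1], [2, 5, 5, 5, 2], [1, 4, 1]])
    def test_symmetric_series_ve_equals_vr(self, extents):
        trap = fit_trapezoid(make_series(extents))
        assert trap.Ve == pytest.approx(trap.Vr)

    def test_all_zero_raises(self):
        with pytest.raises(NoExtensionError):
            fit_trapezoid(make_series([0, 0]))


class TestModelCurve:
    def test_triangle_reproduces_fit_points(self):
        s = make_series([2, 4, 2])
        tri = fit_triangle(s)
        np.testing.assert_allclose(model_curve(tri, s.times), s.extents, atol=1e-12)
        assert model_curve(tri, [0.0])[0] == pytest.approx(2.0)

    def test_zero_at_origin_end_and_outside(self):
        tri = fit_triangle(make_series([2, 4, 2]))
        assert model_curve(tri, [tri.t_origin, tri.t_end, -100.0, 100.0]) == pytest.approx(
            [0, 0, 0, 0]
        )
        trap = fit_trapezoid(make_series([3, 6, 6, 6, 3]))
        assert model_curve(trap, [trap.t_origin, trap.t_end]) == pytest.approx([0, 0])

    def test_emax_at_peak(self):
        tri = fit_triangle(make_series([2, 4, 2]))
        assert model_curve(tri, [tri.t_peak])[0] == pytest.approx(tri.Emax)

    def test_continuity(self):
        s = make_series([1, 3, 5, 5, 5, 2])
        for model in (fit_triangle(s), fit_trapezoid(s)):
            t = np.linspace(model.t_origin - 2, model.t_end + 2, 4001)
            y = model_curve(model, t)
            assert np.max(np.abs(np.diff(y))) < 0.1  # no jumps at this resolution


class TestClassify:
    def test_noiseless_triangle_ties_to_triangle(self):
        fit = classify_dynamics(make_series([2, 4, 2]))
        assert fit.model_label == "triangle"
        assert fit.rmse_triangle == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_trapezoid_wins(self):
        fit = classify_dynamics(make_series([3, 6, 6, 6, 3]))
        assert fit.model_label == "trapezoid"
        assert fit.rmse_trapezoid == pytest.approx(0.0, abs=1e-12)
        assert fit.rmse_trapezoid < fit.rmse_triangle

    def test_translation_invariance(self, meta):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            base = rng.uniform(0, 40, size=(n, 2))
            tip = base + rng.uniform(-5, 5, size=(n, 2))
            s0 = series_from_coords(base.tolist(), tip.tolist(), meta)
            shift = rng.uniform(-20, 20, size=2)
            s1 = series_from_coords(
                (base + shift).tolist(), (tip + shift).tolist(), meta
            )
            try:
                f0 = classify_dynamics(s0)
            except NoExtensionError:
                continue
            f1 = classify_dynamics(s1)
            assert f0.model_label == f1.model_label


def grid_triangle(n_e, n_r, emax, dt=2.0, t_origin=0.0):
    return TriangleModel(
        t_origin=t_origin,
        t_peak_first=t_origin + n_e * dt,
        t_peak_last=t_origin + n_e * dt,
        t_end=t_origin + (n_e + n_r) * dt,
        Emax=emax,
        Ve=emax / (n_e * dt),
        Vr=emax / (n_r * dt),
        lifetime=(n_e + n_r) * dt,
    )


def grid_trapezoid(n_e, n_p, n_r, es, dt=2.0, t_origin=0.0):
    n_life = n_e + n_p + n_r
    return TrapezoidModel(
        t_origin=t_origin,
        t_s_start=t_origin + n_e * dt,
        t_s_end=t_origin + (n_e + n_p) * dt,
        t_end=t_origin + n_life * dt,
        Es=es,
        Vs=0.0,
        Ve=es / (n_e * dt),
        Vr=es / (n_r * dt),
        lifetime=n_life * dt,
    )


class TestExactRecovery:
    @given(
        n_e=st.integers(1, 8),
        n_r=st.integers(1, 8),
        emax=st.floats(0.5, 20, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_triangle_roundtrip(self, n_e, n_r, emax):
        model = grid_triangle(n_e, n_r, emax)
        times = 2.0 * np.arange(1, n_e + n_r)
        s = ExtentSeries(times=times, extents=model_curve(model, times), frame_interval=2.0)
        fit = fit_triangle(s)
        assert fit.Emax == pytest.approx(emax, rel=1e-9)
        assert fit.lifetime == pytest.approx(model.lifetime, rel=1e-9)
        assert fit.Ve == pytest.approx(model.Ve, rel=1e-9)
        assert fit.Vr == pytest.approx(model.Vr, rel=1e-9)
        # curve reproduces the observations exactly
        np.testing.assert_allclose(model_curve(fit, times), s.extents, atol=1e-12)

    @given(
        n_e=st.integers(2, 6),
        n_r=st.integers(2, 6),
        extra_p=st.integers(0, 4),
        es=st.floats(0.5, 20, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_trapezoid_roundtrip(self, n_e, n_r, extra_p, es):
        n_p = abs(n_e - n_r) + 2 + extra_p  # plateau straddles half lifetime
        model = grid_trapezoid(n_e, n_p, n_r, es)
        n_life = n_e + n_p + n_r
        times = 2.0 * np.arange(1, n_life)
        s = ExtentSeries(times=times, extents=model_curve(model, times), frame_interval=2.0)
        fit = fit_trapezoid(s)
        assert fit.Es == pytest.approx(es, rel=1e-9)
        assert fit.Ve == pytest.approx(model.Ve, rel=1e-9)
        assert fit.Vr == pytest.approx(model.Vr, rel=1e-9)
        assert fit.lifetime == pytest.approx(model.lifetime, rel=1e-9)

    def test_lifetime_frame_count_identity(self):
        for n in range(2, 12):
            extents = np.concatenate([np.arange(1, n // 2 + 2), np.arange(n - n // 2 - 1, 0, -1)])[:n]
            s = make_series(extents.tolist())
            assert fit_triangle(s).lifetime == (len(s) + 1) * s.frame_interval


class TestSummarize:
    def test_fully_inside_window(self, meta):
        track = make_track(
            [(0, 0)] * 3, [(2, 0), (4, 0), (2, 0)], frames=[5, 6, 7]
        )
        s = summarize_filopodium(track, meta)
        assert s.has_elongation and s.has_retraction
        assert s.Ve is not None and s.Vr is not None
        assert s.Emax == pytest.approx(4.0)
        assert s.lifetime == pytest.approx(8.0)

    def test_present_at_final_frame_no_vr(self, meta):
        track = make_track(
            [(0, 0)] * 3, [(2, 0), (4, 0), (6, 0)], frames=[14, 15, 16]
        )
        s = summarize_filopodium(track, meta)
        assert not s.has_retraction and s.Vr is None
        assert s.has_elongation and s.Ve is not None

    def test_present_at_first_frame_no_ve(self, meta):
        track = make_track(
            [(0, 0)] * 3, [(6, 0), (4, 0), (2, 0)], frames=[1, 2, 3]
        )
        s = summarize_filopodium(track, meta)
        assert not s.has_elongation and s.Ve is None
        assert s.has_retraction and s.Vr is not None

    def test_born_fully_extended_mid_window_no_ve(self, meta):
        # first observed extent equals Emax: no elongation phase observed
        track = make_track(
            [(0, 0)] * 3, [(6, 0), (4, 0), (2, 0)], frames=[5, 6, 7]
        )
        s = summarize_filopodium(track, meta)
        assert not s.has_elongation

    def test_generator_truncation_bookkeeping(self, meta):
        # 10 models, exactly 3 of which overrun the window end
        rng = np.random.default_rng(0)
        cfg = fd.GeneratorConfig(seed=0)
        n_vr = 0
        for i in range(10):
            t_origin = 4.0 + 2.0 * i
            model = grid_triangle(3, 4, 5.0, t_origin=t_origin)
            track, record = fd.gen_track(model, cfg, rng, filopodium_id=i + 1)
            s = summarize_filopodium(track, meta)
            assert record.truncated_end == (model.t_end > 30.0)
            if s.Vr is not None:
                n_vr += 1
        # lifetime 14 min: t_end = t_origin + 14 > 30 for the last 3 births
        expected_truncated = sum(1 for i in range(10) if 4.0 + 2.0 * i + 14.0 > 30.0)
        assert expected_truncated == 3
        assert n_vr == 10 - expected_truncated
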