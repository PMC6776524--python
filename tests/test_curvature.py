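"""Leaflet assignment, headgroup gridding, Gaussian dome fit, curvature radius."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import piezomd as pm
from piezomd.curvature import FLAT_RADIUS, HeadgroupGrid
from piezomd.synthetic import DomeSpec, make_dome_membrane


def _grid_from_surface(fn, extent=200.0, spacing=4.6):
    xs = np.arange(-extent / 2, extent / 2 + spacing, spacing)
    XX, YY = np.meshgrid(xs, xs)
    return HeadgroupGrid(spacing, xs[0], xs[0], len(xs), len(xs), fn(XX, YY))


class TestKernelSizeRule:
    @pytest.mark.parametrize("nx,ny,expected", [
        (52, 50, 13),   # the published grid: ceil(sqrt(2600)/4)
        (4, 4, 1),
        (10, 40, 5),    # ceil(sqrt(400)/4)
    ])
    def test_values(self, nx, ny, expected):
        assert pm.kernel_size_rule(nx, ny) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            pm.kernel_size_rule(0, 5)


class TestHeightGrid:
    def test_tiling_gives_nine_copies(self):
        pts = np.random.default_rng(0).uniform(0, 50, (17, 3))
        assert len(pm.tile_periodic_images(pts, (50.0, 50.0))) == 9 * 17

    def test_flat_plane_constant_before_and_after_smoothing(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.uniform(-40, 40, 300),
                               rng.uniform(-40, 40, 300),
                               np.full(300, 12.0)])
        for smooth in (False, True):
            grid = pm.build_height_grid(pts, (80.0, 80.0), smooth=smooth)
            np.testing.assert_allclose(grid.heights, 12.0, atol=1e-9)

    def test_wrap_smoothing_preserves_mean(self):
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.uniform(-40, 40, 400),
                               rng.uniform(-40, 40, 400),
                               rng.normal(10.0, 3.0, 400)])
        raw = pm.build_height_grid(pts, (80.0, 80.0), smooth=False)
        sm = pm.build_height_grid(pts, (80.0, 80.0), smooth=True)
        assert sm.heights.mean() == pytest.approx(raw.heights.mean(), abs=1e-9)

    def test_vertical_offset_equivariance(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.uniform(-40, 40, 400),
                               rng.uniform(-40, 40, 400),
                               rng.normal(0.0, 2.0, 400)])
        g0 = pm.build_height_grid(pts, (80.0, 80.0), smooth=False)
        shifted = pts.copy()
        shifted[:, 2] += 7.5
        g1 = pm.build_height_grid(shifted, (80.0, 80.0), smooth=False)
        np.testing.assert_allclose(g1.heights, g0.heights + 7.5, atol=1e-9)
        f0, f1 = pm.fit_dome(g0), pm.fit_dome(g1)
        assert f1.z0 - f0.z0 == pytest.approx(7.5, abs=1e-6)
        assert f1.zh == pytest.approx(f0.zh, abs=1e-6)

    def test_bad_spacing_and_too_few_points(self):
        pts = np.zeros((10, 3))
        with pytest.raises(ValueError):
            pm.build_height_grid(pts, (50.0, 50.0), spacing=-1.0)
        with pytest.raises(ValueError):
            pm.build_height_grid(pts[:3], (50.0, 50.0))


class TestDomeFit:
    def test_recovers_noiseless_surface(self):
        true = dict(z0=20.0, zh=-30.0, rx=0.0, ry=0.0, sigma=70.0)

        def surface(x, y):
            return true["z0"] + true["zh"] * np.exp(
                -((x - true["rx"]) ** 2 + (y - true["ry"]) ** 2) / true["sigma"] ** 2)

        fit = pm.fit_dome(_grid_from_surface(surface, extent=280.0))
        for key in true:
            assert getattr(fit, key) == pytest.approx(true[key], rel=1e-3, abs=1e-3)
        assert fit.residual < 1e-6

    def test_flat_grid_gives_infinite_radius(self):
        fit = pm.fit_dome(_grid_from_surface(lambda x, y: np.full_like(x, 5.0)))
        assert abs(fit.zh) < 1e-6
        assert fit.R == FLAT_RADIUS

    def test_translation_invariance(self):
        def surface(x, y):
            return 10.0 - 25.0 * np.exp(-(x**2 + y**2) / 60.0**2)

        def shifted(x, y):
            return surface(x - 50.0, y - 50.0)

        f0 = pm.fit_dome(_grid_from_surface(surface, extent=260.0))
        xs = np.arange(-130.0 + 50.0, 130.0 + 50.0 + 4.6, 4.6)
        XX, YY = np.meshgrid(xs, xs)
        g1 = HeadgroupGrid(4.6, xs[0], xs[0], len(xs), len(xs), shifted(XX, YY))
        f1 = pm.fit_dome(g1)
        assert f1.sigma == pytest.approx(f0.sigma, rel=1e-6)
        assert f1.zh == pytest.approx(f0.zh, rel=1e-6)
        assert f1.rx - f0.rx == pytest.approx(50.0, abs=1e-4)
        assert f1.ry - f0.ry == pytest.approx(50.0, abs=1e-4)


class TestCurvatureRadius:
    def test_dome_regime_value(self):
        # d = -2(-30)/70² = 0.0122449; R = (1+d²)^1.5/d ≈ 81.685 Å ≈ 8.2 nm
        assert pm.curvature_radius(-30.0, 70.0) == pytest.approx(81.685, abs=0.0005)

    def test_flat_is_infinite(self):
        assert pm.curvature_radius(0.0, 70.0) == FLAT_RADIUS

    def test_sigma_doubling_quadruples_radius_asymptotically(self):
        r1 = pm.curvature_radius(-30.0, 70.0)
        r2 = pm.curvature_radius(-30.0, 140.0)
        assert r2 / r1 == pytest.approx(4.0, rel=1e-3)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            pm.curvature_radius(-30.0, 0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(zh=st.floats(-80.0, 80.0), sigma=st.floats(5.0, 200.0))
    def test_matches_symbolic_closed_form(self, zh, sigma):
        import sympy

        zh_s, sig_s = sympy.Float(zh, 30), sympy.Float(sigma, 30)
        d = -2 * zh_s / sig_s**2
        if d == 0:
            assert pm.curvature_radius(zh, sigma) == FLAT_RADIUS
        else:
            expected = float((1 + d**2) ** sympy.Rational(3, 2) / d)
            assert pm.curvature_radius(zh, sigma) == pytest.approx(expected, rel=1e-12)


class TestLeaflets:
    def _two_up_two_down(self):
        rows, coords = [], []
        for i, up in enumerate([True, True, False, False]):
            rows.append(("PO4", "P", i + 1, "POP", "M", i))
            rows.append(("C4A", "C", i + 1, "POP", "M", i))
            z_head = 20.0 if up else -20.0
            z_tail = z_head + (-8.0 if up else 8.0)
            coords += [[10.0 * i, 0.0, z_head], [10.0 * i, 0.0, z_tail]]
        names, elements, resids, resnames, chains, mols = zip(*rows)
        top = pm.Topology(np.array(names, dtype=object), np.array(elements, dtype=object),
                          np.array(resids), np.array(resnames, dtype=object),
                          np.array(chains, dtype=object), np.array(mols))
        return pm.Trajectory(top, np.array(coords)[None], np.full((1, 3), 60.0),
                             np.array([0.0]))

    def test_head_up_head_down(self):
        asg = pm.assign_leaflets(self._two_up_two_down(), pm.LipidConfig())
        assert list(asg.labels) == ["upper", "upper", "lower", "lower"]

    def test_all_up(self):
        traj = self._two_up_two_down()
        traj.coords[0, 1::2, 2] = traj.coords[0, 0::2, 2] - 8.0  # tails below heads
        asg = pm.assign_leaflets(traj, pm.LipidConfig())
        assert set(asg.labels) == {"upper"}

    def test_generator_labels_recovered(self):
        traj, truth = make_dome_membrane(DomeSpec(seed=0, noise_sd=1.0))
        asg = pm.assign_leaflets(traj, truth.config)
        agree = np.mean(asg.labels == truth.labels)
        assert agree >= 0.99


class TestCurvatureTimeseries:
    def test_static_dome_constant_radius(self):
        traj, truth = make_dome_membrane(DomeSpec(seed=1, noise_sd=0.0, n_frames=5,
                                                  box=(280.0, 280.0, 180.0)))
        series = pm.curvature_timeseries(traj, truth.config, smooth_grid=False,
                                         span=None)
        upper = series.table[series.table.leaflet == "upper"].R_A.to_numpy()
        np.testing.assert_allclose(upper, upper[0], rtol=1e-6)
        # at the default 1/(8 Å)² lipid density the piecewise-linear
        # interpolation slightly broadens the dome; stay within 2%
        assert upper[0] == pytest.approx(truth.R[0], rel=2e-2)

    def test_flattening_radius_monotone_and_accurate(self):
        traj, truth = make_dome_membrane(DomeSpec(seed=2, noise_sd=0.0, n_frames=8,
                                                  flatten_to=-6.0))
        series = pm.curvature_timeseries(traj, truth.config, smooth_grid=False,
                                         span=None)
        upper = series.table[series.table.leaflet == "upper"].R_A.to_numpy()
        assert np.all(np.diff(upper) > 0)
        np.testing.assert_allclose(upper, truth.R, rtol=0.05)

    def test_leaflet_pipelines_independent(self):
        spec = DomeSpec(seed=3, noise_sd=1.0, n_frames=2)
        traj, truth = make_dome_membrane(spec)
        series = pm.curvature_timeseries(traj, truth.config, smooth_grid=False,
                                         span=None)
        # scramble every lower-leaflet lipid's head height
        asg = pm.assign_leaflets(traj, truth.config)
        rng = np.random.default_rng(99)
        for mol in asg.indices("lower"):
            traj.coords[:, mol, 2] += rng.normal(0, 3.0)
        series2 = pm.curvature_timeseries(traj, truth.config, smooth_grid=False,
                                          span=None)
        up1 = series.table[series.table.leaflet == "upper"].R_A.to_numpy()
        up2 = series2.table[series2.table.leaflet == "upper"].R_A.to_numpy()
        np.testing.assert_allclose(up1, up2, rtol=1e-12)

    def test_full_span_smoother_matches_linear_trend(self):
        traj, truth = make_dome_membrane(DomeSpec(seed=4, noise_sd=0.5, n_frames=12,
                                                  flatten_to=-15.0))
        series = pm.curvature_timeseries(traj, truth.config, smooth_grid=False,
                                         span=1.0)
        tab = series.table[series.table.leaflet == "upper"]
        t, r = tab.time_ns.to_numpy(), tab.R_nm.to_numpy()
        coef = np.polyfit(t, r, 1)
        trend = np.polyval(coef, t)
        resid = np.max(np.abs(tab.R_nm_smoothed.to_numpy() - trend))
        assert resid <= 0.1 * (r.max() - r.min())
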