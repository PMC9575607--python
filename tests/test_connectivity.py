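"""ROI masks, nuisance regression, windowed correlation, streaming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tacsloop.connectivity import (
    RoiMaskSpec,
    build_nuisance_regressors,
    fisher_z,
    residualize,
    score_block,
    sphere_mask,
    windowed_connectivity,
)
from tacsloop.params import StimParams
from tacsloop.schedule import block_window_samples, build_run_schedule
from tacsloop.simulate import NuisanceModel, RoiTimeSeries, SurfaceModel, simulate_run


def _toy_timeseries(n=40, tr=2.0, seed=0, cardiac=None, resp=None):
    rng = np.random.default_rng(seed)
    return RoiTimeSeries(
        tr=tr,
        data=rng.normal(size=(n, 2)),
        motion=rng.normal(size=(n, 6)),
        wm=rng.normal(size=n),
        csf=rng.normal(size=n),
        cardiac_phase=np.zeros(n) if cardiac is None else cardiac,
        resp_phase=np.zeros(n) if resp is None else resp,
    )


class TestSphereMask:
    def test_matches_brute_force_count(self):
        spec = RoiMaskSpec(
            center_mm=(-45.0, 49.0, 27.0),
            radius_mm=10.0,
            voxel_size_mm=2.0,
            origin_mm=(-65.0, 29.0, 7.0),
            shape=(21, 21, 21),
        )
        mask = sphere_mask(spec)
        # brute force over every voxel center
        count = 0
        origin = np.array(spec.origin_mm)
        for i in range(spec.shape[0]):
            for j in range(spec.shape[1]):
                for k in range(spec.shape[2]):
                    p = origin + 2.0 * np.array([i, j, k])
                    count += np.sum((p - spec.center_mm) ** 2) <= 100.0
        assert mask.sum() == count

    def test_volume_close_to_continuum_at_1mm(self):
        """At 1-mm voxels the 10-mm sphere volume is within 5% of
        (4/3) pi r^3 (2-mm grids with half-voxel offsets can overcount by
        slightly more, a discretization artifact)."""
        spec = RoiMaskSpec(
            center_mm=(0.0, 0.0, 0.0),
            radius_mm=10.0,
            voxel_size_mm=1.0,
            origin_mm=(-15.0, -15.0, -15.0),
            shape=(31, 31, 31),
        )
        mask = sphere_mask(spec)
        assert mask.sum() * 1.0 == pytest.approx(4 / 3 * np.pi * 1000, rel=0.05)

    def test_tiny_radius_on_voxel_center_is_one_voxel(self):
        spec = RoiMaskSpec(
            center_mm=(0.0, 0.0, 0.0),
            radius_mm=0.5,
            voxel_size_mm=2.0,
            origin_mm=(-10.0, -10.0, -10.0),
            shape=(11, 11, 11),
        )
        mask = sphere_mask(spec)
        assert mask.sum() == 1

    def test_center_outside_grid_is_empty(self):
        spec = RoiMaskSpec(
            center_mm=(500.0, 0.0, 0.0),
            radius_mm=5.0,
            voxel_size_mm=2.0,
            origin_mm=(0.0, 0.0, 0.0),
            shape=(10, 10, 10),
        )
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                sphere_mask(spec)


class TestNuisanceRegressors:
    def test_column_layout(self):
        ts = _toy_timeseries(n=20)
        d = build_nuisance_regressors(ts, poly_order=3, retroicor_order=2)
        assert d.shape == (20, 4 + 6 + 2 + 8)
        # P0 = ones, P1 linear -1..1 with zero mean on an even count
        assert np.allclose(d[:, 0], 1.0)
        assert d[0, 1] == pytest.approx(-1.0) and d[-1, 1] == pytest.approx(1.0)
        assert abs(d[:, 1].mean()) < 1e-12
        assert np.allclose(d[:, 4:10], ts.motion)

    def test_constant_phase_retroicor_columns(self):
        """cos(k*0) = 1, sin(k*0) = 0 for the zero-phase trace."""
        ts = _toy_timeseries(n=10)
        d = build_nuisance_regressors(ts, poly_order=0, retroicor_order=2)
        card = d[:, 9:13]  # after P0 + motion(6) + wm + csf
        assert np.allclose(card[:, 0], 1.0) and np.allclose(card[:, 1], 0.0)
        assert np.allclose(card[:, 2], 1.0) and np.allclose(card[:, 3], 0.0)

    def test_poly_only_intercept(self):
        ts = _toy_timeseries(n=10)
        d = build_nuisance_regressors(ts, poly_order=0, retroicor_order=0)
        assert d.shape[1] == 1 + 6 + 2
        assert np.allclose(d[:, 0], 1.0)


class TestResidualize:
    def test_constant_series_intercept_only(self):
        x = np.full((10, 1), 3.7)
        resid = residualize(x, np.ones((10, 1)))
        assert np.allclose(resid, 0.0, atol=1e-12)

    def test_series_equal_to_design_column(self, rng):
        col = rng.normal(size=(30, 1))
        design = np.column_stack([np.ones(30), col[:, 0]])
        assert np.allclose(residualize(col, design), 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        """Independent solve of (D'D) beta = D'y, n = 50, k = 5."""
        d = rng.normal(size=(50, 5))
        y = rng.normal(size=(50, 2))
        beta = np.linalg.solve(d.T @ d, d.T @ y)
        assert np.allclose(residualize(y, d), y - d @ beta, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        d = rng.normal(size=(60, 8))
        y = rng.normal(size=(60, 2))
        resid = residualize(y, d)
        dots = d.T @ resid
        assert np.max(np.abs(dots)) < 1e-8 * np.linalg.norm(y)

    def test_idempotent(self, rng):
        d = rng.normal(size=(40, 4))
        y = rng.normal(size=(40, 2))
        once = residualize(y, d)
        twice = residualize(once, d)
        assert np.allclose(once, twice, atol=1e-10)

    def test_underdetermined_rejected(self, rng):
        with pytest.raises(ValueError):
            residualize(rng.normal(size=(5, 1)), rng.normal(size=(5, 6)))

    def test_rank_deficient_design_warns_and_projects(self, rng):
        base = rng.normal(size=(30, 3))
        design = np.column_stack([base, base[:, 0] + base[:, 1]])
        y = rng.normal(size=(30, 1))
        with pytest.warns(UserWarning, match="rank"):
            resid = residualize(y, design)
        assert np.max(np.abs(base.T @ resid)) < 1e-8 * np.linalg.norm(y)


class TestWindowedConnectivity:
    def test_identical_channels_clip(self):
        x = np.arange(10.0)
        out = windowed_connectivity(np.column_stack([x, x]), (0, 10), 0)
        assert out.valid and out.r == pytest.approx(1.0)
        # finite z from the documented clip at |r| = 1 - 1e-7
        assert out.z == pytest.approx(0.5 * np.log((2 - 1e-7) / 1e-7))

    def test_exact_r09_gives_z_14722(self, rng):
        """Vectors constructed with sample correlation exactly 0.9."""
        x = rng.normal(size=20)
        g = rng.normal(size=20)
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        gc = g - g.mean()
        gc -= (gc @ xc) * xc
        gc /= np.linalg.norm(gc)
        y = 0.9 * xc + np.sqrt(1 - 0.81) * gc
        out = windowed_connectivity(np.column_stack([x, y]), (0, 20), 3)
        assert out.r == pytest.approx(0.9, abs=1e-12)
        assert out.z == pytest.approx(1.4722, abs=1e-4)

    def test_orthogonal_channels_give_zero(self):
        x = np.array([1.0, -1.0] * 5)
        y = np.array([1.0, 1.0, -1.0, -1.0] * 2 + [1.0, 1.0])
        y = y - y.mean()
        y -= (y @ (x - x.mean())) / np.sum((x - x.mean()) ** 2) * (x - x.mean())
        out = windowed_connectivity(np.column_stack([x, y]), (0, 10), 0)
        assert out.z == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_marks_invalid(self):
        flat = np.column_stack([np.ones(10), np.arange(10.0)])
        out = windowed_connectivity(flat, (0, 10), 2)
        assert not out.valid and out.r is None and out.z is None

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            windowed_connectivity(np.zeros((10, 2)), (0, 3), 0)

    @given(r=st.floats(min_value=-0.999, max_value=0.999))
    @settings(deadline=None, max_examples=50)
    def test_fisher_transform_is_odd_and_increasing(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r))
        assert fisher_z(min(r + 1e-3, 0.9995)) > fisher_z(r)


class TestOnlineScoring:
    def test_streaming_no_lookahead(self, standard_run, clean_surface, no_nuisance):
        """Scoring block b from a feed truncated at its window end equals
        scoring from the complete run."""
        params = [StimParams(6, 0)] * 15
        ts = simulate_run(standard_run, clean_surface, params, seed=6, nuisance=no_nuisance)
        for b in (0, 7, 14):
            _, w1 = block_window_samples(standard_run.blocks[b], standard_run.tr, run=standard_run)
            full = score_block(ts, standard_run, b)
            trunc = score_block(ts.truncated(w1), standard_run, b)
            assert trunc.z == pytest.approx(full.z)

    def test_end_to_end_z_recovery(self, no_nuisance):
        """Mean scored z across 50 blocks at known r is within 2 SE of
        atanh(r), SE = 1/sqrt((n-3) * n_blocks)."""
        r = 0.6
        run = build_run_schedule(n_blocks=50)
        m = SurfaceModel(r_max=r, r_base=0.0, width_f=1e9, width_phi=1e9, noise_sd=0.0)
        ts = simulate_run(run, m, [StimParams(6, 0)] * 50, seed=8, nuisance=no_nuisance)
        zs = [score_block(ts, run, b).z for b in range(50)]
        se = 1.0 / np.sqrt(7 * 50)
        # small-sample atanh bias ~ r / (2 (n-1)) inflates the band slightly
        assert np.mean(zs) == pytest.approx(np.arctanh(r), abs=2 * se + r / 18)

    def test_nuisance_regression_improves_noisy_estimates(self, standard_run):
        """With strong structured nuisance, residualized scoring recovers the
        coupling better than raw correlation."""
        m = SurfaceModel(r_max=0.7, r_base=0.0, noise_sd=0.0)
        heavy = NuisanceModel(drift_amp=3.0, motion_amp=2.0, wmcsf_amp=2.0, physio_amp=2.0)
        params = [StimParams(6, 0)] * 15
        err_clean, err_raw = [], []
        for seed in range(10):
            ts = simulate_run(standard_run, m, params, seed=seed, nuisance=heavy)
            for b in range(3, 15):
                target = np.arctanh(0.7)
                err_clean.append(abs(score_block(ts, standard_run, b).z - target))
                err_raw.append(
                    abs(score_block(ts, standard_run, b, residualize_first=False).z - target)
                )
        assert np.mean(err_clean) < np.mean(err_raw)
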