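"""HRF, GLM, fixed effects, thresholding, Dice."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import blurkit as bk
from blurkit.synth import _boxcar_regressor


@pytest.fixture(scope="module")
def design():
    return bk.BlockDesign.blocks(60, TR=2.0, block_s=16.0)


@pytest.fixture(scope="module")
def hrf():
    return bk.HRFParams()


@pytest.fixture(scope="module")
def mesh():
    white, _ = bk.make_cortical_sheet(
        bk.CorticalSheetSpec(extent=24.0), seed=0)
    return white


class TestGammaHRF:
    def test_peak_before_delay(self, hrf):
        k = bk.gamma_hrf(hrf, dt=0.01)
        t_peak = float(np.argmax(k)) * 0.01
        # gamma mode = delay - scale (for shape > 1), here ~1.56 s
        shape = hrf.delay ** 2 / hrf.dispersion ** 2
        scale = hrf.dispersion ** 2 / hrf.delay
        assert t_peak == pytest.approx((shape - 1) * scale, abs=0.02)
        assert 1.0 < t_peak < hrf.delay

    def test_unit_area(self, hrf):
        k = bk.gamma_hrf(hrf, dt=0.05)
        assert np.sum(k) * 0.05 == pytest.approx(1.0, abs=1e-6)
        assert k[0] == 0.0

    def test_dt_halves_sample_count(self, hrf):
        k1 = bk.gamma_hrf(hrf, dt=0.1, duration=20)
        k2 = bk.gamma_hrf(hrf, dt=0.2, duration=20)
        assert len(k1) == 2 * len(k2)
        # unit-area normalization is discrete, so shapes agree to ~dt
        assert np.allclose(k1[::2], k2, rtol=1e-3)


class TestFitGLM:
    def test_null_calibration(self, design, hrf, mesh):
        rng = np.random.default_rng(11)
        series = bk.SurfaceMap(rng.normal(size=(mesh.n_vertices, 60)), mesh)
        amap = bk.fit_glm(series, design, hrf)
        frac = float(np.mean(amap.p < 0.05))
        se = np.sqrt(0.05 * 0.95 / mesh.n_vertices)
        assert abs(frac - 0.05) < 3 * se

    def test_noiseless_recovery(self, design, hrf, mesh):
        reg = _boxcar_regressor(design, bk.gamma_hrf(hrf), 0.1)
        y = 7.0 + np.outer(np.full(mesh.n_vertices, 1.0), reg)
        amap = bk.fit_glm(bk.SurfaceMap(y, mesh), design, hrf)
        assert np.allclose(amap.beta, 1.0, atol=1e-6)
        assert amap.dof == 57

    def test_power_increases_with_amplitude(self, design, hrf, mesh):
        rng = np.random.default_rng(3)
        reg = _boxcar_regressor(design, bk.gamma_hrf(hrf), 0.1)
        noise = rng.normal(size=(mesh.n_vertices, 60))
        power = []
        for amp in (0.1, 0.3, 0.6):
            y = amp * reg + noise
            amap = bk.fit_glm(bk.SurfaceMap(y, mesh), design, hrf)
            power.append(float(np.mean(amap.p < 0.01)))
        assert power[0] < power[1] < power[2]

    def test_p_and_t_consistent(self, design, hrf, mesh):
        from scipy import stats
        rng = np.random.default_rng(4)
        series = bk.SurfaceMap(rng.normal(size=(mesh.n_vertices, 60)), mesh)
        amap = bk.fit_glm(series, design, hrf)
        expected = 2 * stats.t.sf(np.abs(amap.t), amap.dof)
        assert np.allclose(amap.p, expected)


class TestFixedEffects:
    def test_self_combination_raises_t(self, design, hrf, mesh):
        rng = np.random.default_rng(5)
        reg = _boxcar_regressor(design, bk.gamma_hrf(hrf), 0.1)
        y = 0.5 * reg + rng.normal(size=(mesh.n_vertices, 60))
        amap = bk.fit_glm(bk.SurfaceMap(y, mesh), design, hrf)
        c = bk.fixed_effects_combine([amap, amap])
        assert np.allclose(c.beta, amap.beta)
        assert c.dof == 2 * amap.dof
        assert np.all(np.abs(c.t) >= np.abs(amap.t))

    def test_equal_variance_mean(self, mesh):
        a = bk.ActivationMap(np.full(5, 1.0), np.full(5, 0.2),
                             np.zeros(5), np.full(5, 0.5), 10)
        b = bk.ActivationMap(np.full(5, 3.0), np.full(5, 0.2),
                             np.zeros(5), np.full(5, 0.5), 10)
        c = bk.fixed_effects_combine([a, b])
        assert np.allclose(c.beta, 2.0)

    def test_t_grows_sqrt_k(self, design, hrf, mesh):
        rng = np.random.default_rng(6)
        reg = _boxcar_regressor(design, bk.gamma_hrf(hrf), 0.1)
        maps = []
        for _ in range(4):
            y = 0.4 * reg + rng.normal(size=(mesh.n_vertices, 60))
            maps.append(bk.fit_glm(bk.SurfaceMap(y, mesh), design, hrf))
        t1 = np.median(np.abs(maps[0].t))
        t4 = np.median(np.abs(bk.fixed_effects_combine(maps).t))
        assert t4 == pytest.approx(2 * t1, rel=0.35)


class TestBinarizeDice:
    def test_singletons_removed(self, mesh, design, hrf):
        p = np.ones(mesh.n_vertices)
        p[10] = 1e-6  # isolated survivor
        amap = bk.ActivationMap(np.zeros_like(p), np.ones_like(p),
                                np.zeros_like(p), p, 50, mesh)
        mask = bk.binarize(amap, 0.001, min_cluster=2)
        assert not mask.values.any()

    def test_stricter_threshold_subset(self, mesh, design, hrf):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=mesh.n_vertices)
        amap = bk.ActivationMap(np.zeros_like(p), np.ones_like(p),
                                np.zeros_like(p), p, 50, mesh)
        loose = bk.binarize(amap, 0.2, min_cluster=1)
        strict = bk.binarize(amap, 0.05, min_cluster=1)
        assert np.all(loose.values[strict.values])

    def test_dice_identical_and_disjoint(self, mesh):
        a = np.zeros(mesh.n_vertices, bool)
        a[:20] = True
        b = np.zeros(mesh.n_vertices, bool)
        b[20:40] = True
        sa, sb = bk.SurfaceMap(a, mesh), bk.SurfaceMap(b, mesh)
        assert bk.dice(sa, sa).dice == 1.0
        assert bk.dice(sa, sb).dice == 0.0
        empty = bk.SurfaceMap(np.zeros(mesh.n_vertices, bool), mesh)
        r = bk.dice(empty, empty)
        assert r.dice == 0.0 and r.empty_union

    def test_dice_formula(self, mesh):
        a = np.zeros(mesh.n_vertices, bool)
        b = np.zeros(mesh.n_vertices, bool)
        a[:10] = True
        b[5:15] = True
        r = bk.dice(bk.SurfaceMap(a, mesh), bk.SurfaceMap(b, mesh))
        assert r.dice == pytest.approx(0.5)
        assert (r.n_a, r.n_b, r.n_intersect) == (10, 10, 5)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 20 - 1), st.integers(0, 2 ** 20 - 1))
    def test_dice_symmetry(self, bits_a, bits_b):
        verts = np.zeros((20, 3))
        verts[:, 0] = np.arange(20)
        mesh = bk.TriangleMesh(verts, [[i, i + 1, (i + 2) % 20]
                                       for i in range(18)])
        a = np.array([(bits_a >> i) & 1 for i in range(20)], bool)
        b = np.array([(bits_b >> i) & 1 for i in range(20)], bool)
        ra = bk.dice(bk.SurfaceMap(a, mesh), bk.SurfaceMap(b, mesh))
        rb = bk.dice(bk.SurfaceMap(b, mesh), bk.SurfaceMap(a, mesh))
        assert ra.dice == rb.dice
        assert 0.0 <= ra.dice <= 1.0


class TestStrategyComparison:
    def test_unknown_strategy_rejected(self, mesh, design, hrf):
        white, pial = bk.make_cortical_sheet(
            bk.CorticalSheetSpec(extent=24.0), seed=0)
        ta, tb = bk.make_stripe_phantom(white, bk.StripeSpec(stripe_width=3.0))
        g = bk.VoxelGrid.isotropic((32, 32, 24), 1.0)
        with pytest.raises(ValueError):
            bk.strategy_comparison(white, pial, ta, tb, g, design, hrf,
                                   strategies=("warp-drive",))

    def test_threshold_monotonicity_and_columns(self, design, hrf):
        white, pial = bk.make_cortical_sheet(
            bk.CorticalSheetSpec(extent=24.0), seed=0)
        ta, tb = bk.make_stripe_phantom(
            white, bk.StripeSpec(stripe_width=3.0, gap_fraction=0.25))
        g = bk.VoxelGrid.isotropic((32, 32, 24), 1.0)
        df = bk.strategy_comparison(white, pial, ta, tb, g, design, hrf,
                                    strategies=("default",),
                                    thresholds=(0.001, 0.05), seed=2)
        assert set(df["strategy"]) == {"default"}
        strict = df[df.threshold == 0.001].iloc[0]
        loose = df[df.threshold == 0.05].iloc[0]
        assert loose.n_intersect >= strict.n_intersect
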