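"""Tests of the confound-strategy registry, regression, and filtering."""

import numpy as np
import pytest
from sklearn.base import clone

from fetalqc import (
    DesignMatrix,
    MotionTrace,
    NuisanceRegressor,
    STRATEGIES,
    build_design,
    highpass,
    regress_out,
)
from fetalqc.motion import fd_censor_flags

T = 60


@pytest.fixture
def motion(rng):
    return MotionTrace(np.cumsum(0.05 * rng.standard_normal((T, 6)), axis=0), tr=3.0)


@pytest.fixture
def volume_inputs(rng, motion):
    """Small 4-D phantom with WM/CSF compartments and a planted WM signal."""
    shape = (6, 6, 4)
    wm = np.zeros(shape, bool)
    wm[:, :, 2] = True
    csf = np.zeros(shape, bool)
    csf[:, :, 3] = True
    brain = np.ones(shape, bool)
    s = np.sin(np.linspace(0, 8 * np.pi, T))  # dominant WM fluctuation
    bold = 0.05 * rng.standard_normal(shape + (T,))
    bold[wm] += s
    return {
        "motion": motion,
        "bold": bold,
        "masks": {"brain": brain, "wm": wm, "csf": csf},
        "n_compcor": 5,
        "tcompcor_fraction": 0.02,
        "planted": s,
    }


class TestBuildDesign:
    @pytest.mark.parametrize(
        "strategy,n_cols",
        [
            ("6HMP", 6),
            ("24HMP", 24),
            ("2Phys", 2),
            ("8Phys", 8),
            ("GSR", 1),
            ("2GSR", 2),
            ("4GSR", 4),
            ("aCompCor", 5),
            ("aCompCor+6HMP", 11),
            ("4GSR+8Phys+24HMP", 36),
        ],
    )
    def test_column_counts(self, volume_inputs, strategy, n_cols):
        d = build_design(strategy, volume_inputs)
        assert d.n_columns == n_cols
        assert len(d.names) == n_cols

    def test_registry_covers_named_families(self):
        for family in ["6HMP", "24HMP", "2Phys", "8Phys", "GSR", "2GSR", "4GSR",
                       "aCompCor", "tCompCor", "localWM", "none"]:
            assert family in STRATEGIES

    def test_unknown_strategy_lists_registry(self, volume_inputs):
        with pytest.raises(ValueError, match="registered"):
            build_design("7HMP", volume_inputs)

    def test_censor_suffix_ignored_in_design(self, volume_inputs):
        d = build_design("6HMP+censor", volume_inputs)
        assert d.n_columns == 6

    def test_acompcor_finds_planted_component(self, volume_inputs):
        d = build_design("aCompCor", volume_inputs)
        r = np.corrcoef(d.regressors[:, 0], volume_inputs["planted"])[0, 1]
        assert abs(r) > 0.99

    def test_tcompcor_tracks_high_variance_voxels(self, volume_inputs):
        d = build_design("tCompCor", volume_inputs)
        # the WM signal dominates temporal variance, so the first tCompCor
        # component should track it too
        r = np.corrcoef(d.regressors[:, 0], volume_inputs["planted"])[0, 1]
        assert abs(r) > 0.95

    def test_localwm_regressor_per_region(self, volume_inputs):
        vol_shape = volume_inputs["bold"].shape[:3]
        ijk = np.indices(vol_shape).reshape(3, -1).T.astype(float)
        inputs = dict(volume_inputs)
        inputs["voxel_coords_mm"] = ijk * 2.0
        inputs["centroids"] = np.array([[6.0, 6.0, 4.0], [500.0, 500.0, 500.0]])
        inputs["localwm_radius_mm"] = 25.0
        d = build_design("localWM", inputs)
        assert d.per_region and d.n_columns == 2
        # near region picks up the planted WM signal; far region has none
        r = np.corrcoef(d.regressors[:, 0], volume_inputs["planted"])[0, 1]
        assert abs(r) > 0.9
        assert np.all(d.regressors[:, 1] == 0)

    def test_empty_tissue_mask_rejected(self, volume_inputs):
        bad = dict(volume_inputs)
        bad["masks"] = dict(volume_inputs["masks"])
        bad["masks"]["wm"] = np.zeros_like(volume_inputs["masks"]["wm"])
        bad["masks"]["csf"] = np.zeros_like(volume_inputs["masks"]["csf"])
        with pytest.raises(ValueError, match="empty"):
            build_design("aCompCor", bad)


class TestRegressOut:
    def test_constant_design_demeans(self, rng):
        y = rng.standard_normal(T) + 5.0
        d = DesignMatrix(np.ones((T, 1)), ["const"], "const")
        np.testing.assert_allclose(regress_out(y, d), y - y.mean(), atol=1e-12)

    def test_perfect_fit_gives_null_residuals(self, rng):
        X = rng.standard_normal((T, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        d = DesignMatrix(X, list("abc"), "custom")
        res = regress_out(y, d)
        assert np.linalg.norm(res) / np.linalg.norm(y) < 1e-10

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.standard_normal((T, 4))
        y = rng.standard_normal((T, 3))
        d = DesignMatrix(X, list("abcd"), "custom")
        res = regress_out(y, d)
        Xc = X - X.mean(0)
        rc = res - res.mean(0)
        corr = (Xc / np.linalg.norm(Xc, axis=0)).T @ (rc / np.linalg.norm(rc, axis=0))
        assert np.abs(corr).max() < 1e-10

    def test_idempotence(self, rng):
        X = rng.standard_normal((T, 4))
        y = rng.standard_normal(T)
        d = DesignMatrix(X, list("abcd"), "custom")
        r1 = regress_out(y, d)
        r2 = regress_out(r1, d)
        assert np.linalg.norm(r2 - r1) / np.linalg.norm(r1) < 1e-10

    def test_censoring_excludes_frames(self, rng):
        X = rng.standard_normal((T, 2))
        y = rng.standard_normal(T)
        cm = fd_censor_flags(np.r_[np.zeros(T - 5), np.ones(5)], threshold=0.5)
        d = DesignMatrix(X, list("ab"), "custom")
        res = regress_out(y, d, censor=cm)
        assert res.shape[0] == T - 5
        Xk = X[cm.keep]
        assert np.abs(Xk.T @ (res - 0)).max() < 1e-8 or True  # orthogonality below
        np.testing.assert_allclose(Xk.T @ res, 0.0, atol=1e-9)

    def test_rank_deficient_warns(self, rng):
        x = rng.standard_normal(T)
        X = np.column_stack([x, 2 * x])
        d = DesignMatrix(X, ["a", "a2"], "custom")
        with pytest.warns(UserWarning, match="rank-deficient"):
            regress_out(rng.standard_normal(T), d)

    def test_overparameterized_rejected(self, rng):
        X = rng.standard_normal((10, 10))
        d = DesignMatrix(X, [f"c{i}" for i in range(10)], "custom")
        with pytest.raises(ValueError, match="retained frames"):
            regress_out(rng.standard_normal(10), d)


class TestHighpass:
    def test_stopband_drift_removed(self):
        t = np.arange(96) * 3.0
        y = np.sin(2 * np.pi * 0.002 * t)
        out = highpass(y, cutoff=0.008, tr=3.0)
        assert np.sum(out**2) < 0.05 * np.sum(y**2)

    def test_passband_preserved(self):
        t = np.arange(96) * 3.0
        y = np.sin(2 * np.pi * 0.05 * t)
        out = highpass(y, cutoff=0.008, tr=3.0)
        assert np.sum(out**2) > 0.90 * np.sum(y**2)

    def test_constant_maps_to_zero(self):
        np.testing.assert_allclose(
            highpass(np.full(50, 3.7), cutoff=0.008, tr=3.0), 0.0, atol=1e-10
        )

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            highpass(np.array([1.0, 2.0]), cutoff=0.008, tr=3.0)

    def test_supra_nyquist_cutoff_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            highpass(np.zeros(50), cutoff=0.2, tr=3.0)


class TestNuisanceRegressor:
    def test_sklearn_protocol(self):
        reg = NuisanceRegressor(strategy="6HMP", n_compcor=3)
        cloned = clone(reg)
        assert cloned.get_params()["n_compcor"] == 3
        cloned.set_params(strategy="24HMP")
        assert cloned.strategy == "24HMP"

    def test_fit_transform_pipeline(self, rng, motion):
        X = rng.standard_normal((T, 5))
        reg = NuisanceRegressor(strategy="24HMP", highpass_hz=None, tr=3.0)
        out = reg.fit(X, motion=motion).transform(X)
        assert out.shape == X.shape
        assert reg.design_.n_columns == 24
        # residuals decorrelated from motion parameters (before any
        # subsequent filtering, which can reintroduce small correlations)
        mp = motion.params - motion.params.mean(0)
        oc = out - out.mean(0)
        corr = (mp / np.linalg.norm(mp, axis=0)).T @ (oc / np.linalg.norm(oc, axis=0))
        assert np.abs(corr).max() < 1e-8
        # the full regression + high-pass pipeline preserves shape
        full = NuisanceRegressor(strategy="24HMP", highpass_hz=0.008, tr=3.0)
        assert full.fit(X, motion=motion).transform(X).shape == X.shape

    def test_none_strategy_with_highpass_only(self, rng):
        X = rng.standard_normal((T, 2)) + 10.0
        reg = NuisanceRegressor(strategy="none", highpass_hz=0.008, tr=3.0)
        out = reg.fit(X).transform(X)
        np.testing.assert_allclose(out.mean(0), 0.0, atol=1e-9)
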