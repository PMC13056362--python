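import math

import numpy as np
import pytest
from sptmotion.estimation import (
    TrackMotionModel,
    blur_correct_d,
    calibrate_pvalue,
    classification_to_dataframe,
    classify_by_segments,
    classify_track,
    derive_motion,
    fit_model,
)
from sptmotion.io import Track
from sptmotion.simulate import (
    SimConfig,
    _simulate_brownian_batch,
    _simulate_confined_batch,
    _simulate_directed_batch,
    simulate_directed,
)


class TestFitModel:
    def test_frozen_parameter_bit_exact(self, brownian_tracks_2d):
        res = fit_model(brownian_tracks_2d[0], "brownian", init={"d": 0.123}, frozen={"d"})
        assert res.params.d == 0.123
        assert "d" in res.frozen

    def test_deterministic(self, brownian_tracks_2d):
        a = fit_model(brownian_tracks_2d[1], "confined")
        b = fit_model(brownian_tracks_2d[1], "confined")
        assert a.params == b.params and a.llf == b.llf

    def test_freeze_unknown_name(self, brownian_tracks_2d):
        with pytest.raises(ValueError):
            fit_model(brownian_tracks_2d[0], "brownian", frozen={"l"})

    def test_summary_and_bse(self, brownian_tracks_2d):
        res = fit_model(brownian_tracks_2d[0], "brownian")
        text = res.summary()
        assert "logL" in text and "d" in text
        assert res.bse["d"] > 0

    def test_from_dataframe_constructor(self, brownian_tracks_2d):
        import pandas as pd

        t = brownian_tracks_2d[0]
        df = pd.DataFrame(
            dict(track_id=t.track_id, frame=t.frames,
                 x=t.positions[:, 0], y=t.positions[:, 1])
        )
        model = TrackMotionModel.from_dataframe(df, "brownian")
        assert model.fit().llf == pytest.approx(fit_model(t, "brownian").llf)


class TestParameterRecovery:
    def test_confined_recovery(self):
        # substep simulation gives AR(1) frame dynamics with effective
        # confinement 1 - exp(-l); d picks up a small discretization bias
        rng = np.random.default_rng(21)
        cfg = SimConfig(n_steps=200, d=0.1, sigma=0.02, l=0.25, q=0.0)
        obs, _ = _simulate_confined_batch(100, cfg, rng)
        fits = [fit_model(obs[i], "confined") for i in range(100)]
        l_med = np.median([f.params.l for f in fits])
        d_med = np.median([f.params.d for f in fits])
        assert l_med == pytest.approx(1 - math.exp(-0.25), rel=0.10)
        assert d_med == pytest.approx(0.1, rel=0.15)

    def test_confined_recovery_exact_discrete(self):
        rng = np.random.default_rng(22)
        cfg = SimConfig(n_steps=200, d=0.1, sigma=0.02, l=0.25, q=0.0, substeps=1)
        obs, _ = _simulate_confined_batch(80, cfg, rng)
        fits = [fit_model(obs[i], "confined") for i in range(80)]
        assert np.median([f.params.l for f in fits]) == pytest.approx(0.25, rel=0.1)
        assert np.median([f.params.d for f in fits]) == pytest.approx(0.1, rel=0.1)

    def test_directed_speed_recovery(self):
        rng = np.random.default_rng(23)
        cfg = SimConfig(n_steps=30, d=0.0, sigma=0.02, v=0.1)
        obs, _ = _simulate_directed_batch(100, cfg, rng)
        speeds = [
            derive_motion(fit_model(obs[i], "directed")).speed_estimate
            for i in range(100)
        ]
        assert np.median(speeds) == pytest.approx(0.1, rel=0.10)

    def test_rotational_diffusion_recovery(self):
        rng = np.random.default_rng(24)
        cfg = SimConfig(n_steps=200, d=0.0, sigma=0.02, v=0.1, rot_angle_sd=0.2)
        obs, _ = _simulate_directed_batch(60, cfg, rng)
        thetas = [
            derive_motion(fit_model(obs[i], "directed")).rot_angle for i in range(60)
        ]
        assert np.median(thetas) == pytest.approx(0.2, rel=0.20)


class TestDerivedMotion:
    def test_confinement_formulas(self, brownian_tracks_2d):
        fit = fit_model(
            brownian_tracks_2d[0], "confined",
            init=dict(d=0.1, sigma=0.02, l=0.1, q=0.0),
            frozen={"d", "sigma", "l", "q"},
        )
        dm = derive_motion(fit)
        assert dm.conf_sd == pytest.approx(0.1 / math.sqrt(0.2), abs=1e-9)
        assert dm.conf_radius_3sd == pytest.approx(0.67082, abs=1e-4)
        assert dm.conf_diameter == pytest.approx(0.89443, abs=1e-4)

    def test_zero_confinement_flagged(self, brownian_tracks_2d):
        fit = fit_model(
            brownian_tracks_2d[0], "confined",
            init=dict(d=0.1, sigma=0.02, l=0.0, q=0.01),
            frozen={"d", "sigma", "l", "q"},
        )
        dm = derive_motion(fit)
        assert not dm.well_defined and np.isnan(dm.conf_sd)

    def test_chord_equals_speed_gives_sixty_degrees(self):
        # constant-speed track fitted with frozen q chosen so that the
        # per-step chord sqrt(2)*q equals the speed
        t = simulate_directed(SimConfig(n_steps=60, d=0.0, sigma=0.001, v=0.1, seed=3))
        fit = fit_model(t, "directed", init=dict(q=0.1 / math.sqrt(2)), frozen={"q"})
        dm = derive_motion(fit)
        k = dm.speed_estimate
        expected = 2 * math.asin(min(1.0, 0.1 / (2 * k)))
        assert dm.rot_angle == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(math.pi / 3, rel=0.05)


class TestBlurCorrection:
    def test_blur_regime_corrected(self):
        out = blur_correct_d(0.082, 0.01)
        assert out.blur_regime
        assert out.d_corrected == pytest.approx(0.082 * math.sqrt(1.5), abs=1e-6)
        assert out.d_corrected == pytest.approx(0.10043, abs=1e-4)

    def test_static_regime_unchanged(self):
        out = blur_correct_d(0.01, 0.02)
        assert not out.blur_regime and out.d_corrected == 0.01


class TestClassification:
    def test_directed_track_detected(self):
        t = simulate_directed(SimConfig(n_steps=30, d=0.0, sigma=0.02, v=0.1, seed=4))
        res = classify_track(t)
        assert res.label == "directed"
        assert res.rho_directed < 1e-6

    def test_immobile_track_is_brownian_with_bounded_rhos(self, rng):
        pos = rng.normal(0, 0.02, (40, 2))  # pure localization noise
        res = classify_track(Track("still", pos))
        assert res.rho_confined <= 1.0 and res.rho_directed <= 1.0
        assert res.label == "brownian"

    def test_nesting_of_fitted_likelihoods(self, brownian_tracks_2d):
        for t in brownian_tracks_2d[:10]:
            res = classify_track(t)
            assert res.logL_c >= res.logL_b - 1e-6
            assert res.logL_d >= res.logL_b - 1e-6

    def test_certainty_grows_with_track_length(self):
        rng = np.random.default_rng(25)
        means = {}
        for n in (30, 100):
            cfg = SimConfig(n_steps=n, d=0.1, sigma=0.02, l=0.25)
            obs, _ = _simulate_confined_batch(40, cfg, rng)
            logrho = []
            for i in range(40):
                res = classify_track(obs[i])
                logrho.append(min(0.0, res.logL_b - res.logL_c))
            means[n] = np.mean(logrho)
        assert means[100] < means[30]

    def test_short_track_warns(self, rng):
        pos = rng.normal(0, 0.1, (4, 2))
        with pytest.warns(UserWarning):
            classify_track(Track("short", pos))

    def test_bonferroni_threshold(self):
        t = simulate_directed(SimConfig(n_steps=30, d=0.0, sigma=0.02, v=0.1, seed=6))
        res = classify_track(t, alpha=0.05, n_tracks_for_bonferroni=100)
        assert res.threshold == pytest.approx(0.0005)

    def test_dataframe_schema(self, brownian_tracks_2d):
        df = classification_to_dataframe([classify_track(brownian_tracks_2d[0])])
        assert list(df.columns)[:5] == ["track_id", "label", "logL_b", "logL_c", "logL_d"]
        assert df.shape[0] == 1 and np.isfinite(df["d_b"].iloc[0])


class TestSegmentClassification:
    def test_single_segment_equals_whole_track(self):
        t = simulate_directed(SimConfig(n_steps=29, d=0.0, sigma=0.02, v=0.1, seed=7))
        whole = classify_track(t)
        seg = classify_by_segments(t, segment_len=30)
        assert seg.logL_b == pytest.approx(whole.logL_b, abs=1e-9)
        assert seg.logL_d == pytest.approx(whole.logL_d, abs=1e-9)
        assert seg.label == whole.label

    def test_direction_reversal_favors_segments(self, rng):
        # two halves moving in opposite directions at speed 0.1
        n_half = 20
        up = 0.1 * np.arange(n_half + 1)
        down = up[-1] - 0.1 * np.arange(1, n_half + 1)
        x = np.concatenate([up, down])
        pos = np.stack([x, np.zeros_like(x)], axis=1) + rng.normal(0, 0.02, (2 * n_half + 1, 2))
        t = Track("rev", pos)
        whole = classify_track(t)
        seg = classify_by_segments(t, segment_len=n_half)
        assert seg.rho_directed < whole.rho_directed

    def test_too_few_segments(self, rng):
        t = Track("t", rng.normal(0, 0.1, (8, 2)))
        with pytest.raises(ValueError):
            classify_by_segments(t, segment_len=10)


class TestCalibratedPvalue:
    def test_strongly_directed_minimal_pvalue(self):
        t = simulate_directed(SimConfig(n_steps=25, d=0.0, sigma=0.02, v=0.1, seed=8))
        p = calibrate_pvalue(t, n_sims=100, seed=1, alternative="directed")
        assert p == pytest.approx(1 / 101)

    def test_null_pvalues_valid(self):
        # under the Brownian null the calibrated p-value is (conservatively)
        # valid: P(p <= a) <= a. It is not exactly uniform because the
        # boundary MLE puts an atom of the ratio at rho = 1.
        rng = np.random.default_rng(26)
        cfg = SimConfig(n_steps=20, d=0.1, sigma=0.02, substeps=1)
        obs, _ = _simulate_brownian_batch(40, cfg, rng)
        ps = np.array([
            calibrate_pvalue(obs[i], n_sims=120, seed=100 + i, alternative="directed")
            for i in range(40)
        ])
        for a in (0.05, 0.1, 0.25, 0.5):
            se = np.sqrt(a * (1 - a) / ps.size)
            assert np.mean(ps <= a) <= a + 3 * se

    def test_validations(self, brownian_tracks_2d):
        with pytest.raises(ValueError):
            calibrate_pvalue(brownian_tracks_2d[0], n_sims=10)
        with pytest.raises(ValueError):
            calibrate_pvalue(brownian_tracks_2d[0], alternative="ballistic")
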