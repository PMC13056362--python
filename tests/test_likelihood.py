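import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sptmotion.statespace import (
    BrownianParams,
    ConfinedParams,
    DegenerateModelError,
    DirectedParams,
    GaussianMessage,
    StateSpaceSpec,
    gaussian_product,
    loglik_brownian,
    loglik_confined,
    loglik_directed,
    mvn_oracle_loglik,
)


class TestGaussianProduct:
    def test_symmetric_standard_case(self):
        g = gaussian_product(0, 1, 0, 1)
        assert math.exp(g.log_scale) == pytest.approx(1 / math.sqrt(4 * math.pi), rel=1e-12)
        assert g.mean == 0 and g.sd == pytest.approx(1 / math.sqrt(2))

    def test_shifted_means(self):
        g = gaussian_product(1, 1, 3, 1)
        assert g.mean == pytest.approx(2.0)
        assert g.sd**2 == pytest.approx(0.5)
        assert math.exp(g.log_scale) == pytest.approx(math.exp(-1) / math.sqrt(4 * math.pi), rel=1e-12)

    def test_matches_quadrature(self, rng):
        x = np.linspace(-30, 30, 60_001)
        for _ in range(20):
            mf, mg = rng.normal(0, 2, 2)
            sf, sg = rng.uniform(0.3, 3, 2)
            g = gaussian_product(mf, sf, mg, sg)
            f = np.exp(-0.5 * ((x - mf) / sf) ** 2) / (sf * math.sqrt(2 * math.pi))
            h = np.exp(-0.5 * ((x - mg) / sg) ** 2) / (sg * math.sqrt(2 * math.pi))
            eta = np.exp(-0.5 * ((x - g.mean) / g.sd) ** 2) / (g.sd * math.sqrt(2 * math.pi))
            np.testing.assert_allclose(f * h, math.exp(g.log_scale) * eta, atol=1e-8)

    @given(
        mf=st.floats(-10, 10), mg=st.floats(-10, 10),
        sf=st.floats(0.01, 10), sg=st.floats(0.01, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_moment_algebra(self, mf, mg, sf, sg):
        g = gaussian_product(mf, sf, mg, sg)
        assert min(mf, mg) - 1e-9 <= g.mean <= max(mf, mg) + 1e-9
        assert g.sd <= min(sf, sg) + 1e-12
        assert g.sd**2 == pytest.approx(sf**2 * sg**2 / (sf**2 + sg**2))

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            gaussian_product(0, 0, 0, 1)
        with pytest.raises(ValueError):
            GaussianMessage(0.0, 0.0, 0.0)


class TestBrownianLoglik:
    def test_single_step_closed_form(self):
        d, s = 0.1, 0.02
        var = d**2 + 2 * s**2
        expected = -0.5 * (math.log(2 * math.pi * var) + 0.1**2 / var)
        ll = loglik_brownian(np.array([[0.0], [0.1]]), BrownianParams(d, s))
        assert ll == pytest.approx(expected, abs=1e-12)
        assert ll == pytest.approx(0.8822030762583459, abs=1e-9)

    def test_zero_error_independent_displacements(self, rng):
        pos = np.cumsum(rng.normal(0, 0.1, (15, 2)), axis=0)
        d = 0.08
        ll = loglik_brownian(pos, BrownianParams(d, 0.0))
        steps = np.diff(pos, axis=0)
        expected = np.sum(-0.5 * (math.log(2 * math.pi * d**2) + steps**2 / d**2))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_displacement_covariance_structure(self, rng):
        # against an independently assembled displacement MVN:
        # Var = d^2 + 2 sigma^2, lag-1 covariance = -sigma^2
        from scipy.stats import multivariate_normal

        pos = np.cumsum(rng.normal(0, 0.1, (4, 1)), axis=0)
        d, s = 0.1, 0.03
        n = 3
        cov = np.diag(np.full(n, d**2 + 2 * s**2))
        cov += np.diag(np.full(n - 1, -(s**2)), 1) + np.diag(np.full(n - 1, -(s**2)), -1)
        expected = multivariate_normal(mean=np.zeros(n), cov=cov).logpdf(np.diff(pos[:, 0]))
        assert loglik_brownian(pos, BrownianParams(d, s)) == pytest.approx(expected, abs=1e-8)

    def test_too_short_track(self):
        with pytest.raises(ValueError):
            loglik_brownian(np.array([[0.0]]), BrownianParams(0.1, 0.01))


class TestReductions:
    def test_confined_reduces_to_brownian(self, rng):
        pos = np.cumsum(rng.normal(0, 0.1, (20, 2)), axis=0)
        b = loglik_brownian(pos, BrownianParams(0.1, 0.02))
        c = loglik_confined(pos, ConfinedParams(0.1, 0.02, 0.0, 0.0))
        assert c == pytest.approx(b, abs=1e-9)

    def test_directed_reduces_to_brownian(self, rng):
        pos = np.cumsum(rng.normal(0, 0.1, (20, 2)), axis=0)
        b = loglik_brownian(pos, BrownianParams(0.1, 0.02))
        d = loglik_directed(pos, DirectedParams(0.1, 0.02, 0.0, 0.0))
        assert d == pytest.approx(b, abs=1e-9)


class TestOracleEquivalence:
    def test_recurrence_matches_dense_mvn_200_cases(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(1, 7))
            dim = int(rng.integers(1, 4))
            pos = rng.normal(0, 0.3, (n + 1, dim))
            fam = int(rng.integers(0, 3))
            d = float(rng.uniform(0.005, 0.4))
            s = float(rng.uniform(0.003, 0.1))
            if fam == 0:
                p = BrownianParams(d, s)
                ll = loglik_brownian(pos, p)
            elif fam == 1:
                p = ConfinedParams(d, s, float(rng.uniform(1e-4, 0.95)), float(rng.uniform(0, 0.2)))
                ll = loglik_confined(pos, p)
            else:
                p = DirectedParams(d, s, float(rng.uniform(0, 0.3)), float(rng.uniform(0, 0.2)))
                ll = loglik_directed(pos, p)
            oracle = mvn_oracle_loglik(pos, StateSpaceSpec.for_params(p))
            assert ll == pytest.approx(oracle, abs=1e-8), (p, n, dim)

    def test_oracle_quadrature_confined_n1(self):
        # independent check of the oracle itself: direct numerical
        # integration of the hidden-variable product for a 1-step track
        d, s, l, q = 0.12, 0.03, 0.4, 0.05
        c0, c1 = 0.0, 0.15
        q0 = math.sqrt(d**2 / (2 * l) + s**2)
        grid_r = np.linspace(-0.6, 0.6, 401)
        grid_z = np.linspace(-1.2, 1.2, 801)
        grid_h = np.linspace(-1.2, 1.2, 801)

        def norm(x, sd):
            return np.exp(-0.5 * (x / sd) ** 2) / (sd * math.sqrt(2 * math.pi))

        # integrate over r0 first: N(r0; c0, s) * N(z0; r0, d) -> N(z0; c0, sqrt(d^2+s^2))
        Z, H = np.meshgrid(grid_z, grid_h, indexing="ij")
        integrand = (
            norm(Z - c0, math.sqrt(d**2 + s**2))
            * norm(H - c0, q0)
            * norm((1 - l) * Z + l * H - c1, s)
        )
        dz = grid_z[1] - grid_z[0]
        dh = grid_h[1] - grid_h[0]
        quad = integrand.sum() * dz * dh
        p = ConfinedParams(d, s, l, q)
        oracle = mvn_oracle_loglik(np.array([[c0], [c1]]), StateSpaceSpec.for_params(p))
        assert math.log(quad) == pytest.approx(oracle, abs=1e-5)

    def test_oracle_translation_invariance(self):
        p = ConfinedParams(0.1, 0.02, 0.5, 0.0)
        pos = np.array([[0.0], [0.1], [0.05]])
        a = mvn_oracle_loglik(pos, StateSpaceSpec.for_params(p))
        b = mvn_oracle_loglik(pos + 3.7, StateSpaceSpec.for_params(p))
        assert a == pytest.approx(b, abs=1e-10)
        assert np.isfinite(a)


@pytest.mark.parametrize(
    "params, fn",
    [
        (BrownianParams(0.1, 0.02), loglik_brownian),
        (ConfinedParams(0.1, 0.02, 0.3, 0.04), loglik_confined),
        (DirectedParams(0.05, 0.02, 0.08, 0.03), loglik_directed),
    ],
    ids=["brownian", "confined", "directed"],
)
class TestNormalization:
    def test_density_integrates_to_one_n1(self, params, fn):
        c1 = np.linspace(-1.5, 1.5, 3001)
        lls = np.array([fn(np.array([[0.0], [c]]), params) for c in c1])
        total = np.trapezoid(np.exp(lls), c1)
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_density_integrates_to_one_n2(self, params, fn):
        g = np.linspace(-1.2, 1.2, 241)
        dg = g[1] - g[0]
        C1, C2 = np.meshgrid(g, g, indexing="ij")
        vals = np.empty(C1.shape)
        for i in range(C1.shape[0]):
            for j in range(C1.shape[1]):
                vals[i, j] = fn(np.array([[0.0], [C1[i, j]], [C2[i, j]]]), params)
        total = np.exp(vals).sum() * dg * dg
        assert total == pytest.approx(1.0, abs=1e-4)


class TestSymmetries:
    def test_translation_invariance_exact(self, rng):
        pos = np.cumsum(rng.normal(0, 0.1, (25, 2)), axis=0)
        for p, fn in [
            (ConfinedParams(0.1, 0.02, 0.3, 0.02), loglik_confined),
            (DirectedParams(0.05, 0.02, 0.1, 0.02), loglik_directed),
            (BrownianParams(0.1, 0.02), loglik_brownian),
        ]:
            assert fn(pos + 11.0, p) == pytest.approx(fn(pos, p), abs=1e-9)

    def test_rotation_invariance_2d(self, rng):
        pos = np.cumsum(rng.normal(0, 0.1, (25, 2)), axis=0)
        pos[:, 0] += 0.05 * np.arange(25)  # add drift so the test is not vacuous
        th = 0.83
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        rotated = (pos - pos[0]) @ R.T + pos[0]
        for p, fn in [
            (DirectedParams(0.05, 0.02, 0.1, 0.02), loglik_directed),
            (ConfinedParams(0.1, 0.02, 0.3, 0.02), loglik_confined),
        ]:
            assert fn(rotated, p) == pytest.approx(fn(pos, p), abs=1e-9)

    @given(s=st.floats(0.1, 10))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scaling_covariance(self, s):
        rng = np.random.default_rng(9)
        pos = np.cumsum(rng.normal(0, 0.1, (12, 2)), axis=0)
        n, dim = pos.shape[0] - 1, pos.shape[1]
        p1 = ConfinedParams(0.1, 0.02, 0.3, 0.05)
        p2 = ConfinedParams(0.1 * s, 0.02 * s, 0.3, 0.05 * s)
        a = loglik_confined(pos, p1)
        b = loglik_confined(pos * s, p2)
        assert b == pytest.approx(a - n * dim * math.log(s), rel=1e-9, abs=1e-7)


class TestDegenerateInputs:
    def test_all_zero_noise_rejected(self):
        with pytest.raises(DegenerateModelError):
            BrownianParams(0.0, 0.0)

    def test_l_out_of_range(self):
        with pytest.raises(ValueError):
            ConfinedParams(0.1, 0.02, 1.0, 0.0)

    def test_individual_zeros_allowed(self, rng):
        pos = np.cumsum(rng.normal(0, 0.1, (10, 1)), axis=0)
        assert np.isfinite(loglik_brownian(pos, BrownianParams(0.1, 0.0)))
        assert np.isfinite(loglik_confined(pos, ConfinedParams(0.0, 0.02, 0.5, 0.1)))
        assert np.isfinite(loglik_directed(pos, DirectedParams(0.1, 0.0, 0.0, 0.0)))


class TestStateSpaceSpec:
    def test_yaml_round_trip(self):
        spec = StateSpaceSpec.for_params(ConfinedParams(0.1, 0.02, 0.3, 0.04))
        back = StateSpaceSpec.from_yaml(spec.to_yaml())
        assert back == spec
        assert back.latent_names == ["z", "h"]
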