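"""GLM fitting, delay optimization and the three CVR estimators."""

import numpy as np
import pytest

from cvrbh import (
    BoldRun,
    DelaySearchSpec,
    RegressorBuilder,
    UniformSeries,
    fit_glm_single,
    fit_globopt,
    fit_rhsig,
    fit_voxopt,
    optimize_global_delay,
)
from cvrbh.cvr import RHsigCvr, _detrend_rows
from cvrbh.errors import DegenerateRegressorError, DelayRangeWarning


def smooth_builder(tr=2.0, n_frames=60, t0=2.0):
    """A smooth, non-periodic uniform series wrapped in a builder."""
    t = np.arange(0.0, 200.0, 0.1)
    vals = 40 + 3 * np.sin(2 * np.pi * t / 45.0) + 1.5 * np.sin(2 * np.pi * t / 19.0)
    return RegressorBuilder(UniformSeries(vals, dt=0.1), tr, n_frames, t0=t0)


def run_from_voxels(voxels, tr=2.0):
    """voxels: list of %BOLD series -> BoldRun on an (n,1,1) grid."""
    arr = np.asarray(voxels, dtype=float)[:, None, None, :]
    return BoldRun(arr, tr=tr)


class TestFitGlmSingle:
    def test_exact_linear_relation(self):
        x = np.sin(np.arange(20.0))
        beta, r2 = fit_glm_single(0.3 * x + 100.0, x)
        assert beta == pytest.approx(0.3)
        assert r2 == pytest.approx(1.0)

    def test_orthogonal_regressor(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        beta, r2 = fit_glm_single(y, x)
        assert beta == pytest.approx(0.0)
        assert r2 == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.standard_normal(50)
        y = 0.3 * x + 0.2 * rng.standard_normal(50) + 100
        beta, r2 = fit_glm_single(y, x)
        X = np.column_stack([np.ones(50), x])
        coef = np.linalg.solve(X.T @ X, X.T @ y)  # explicit (X'X)^-1 X'y
        resid = y - X @ coef
        r2_oracle = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert beta == pytest.approx(coef[1], rel=1e-10)
        assert r2 == pytest.approx(r2_oracle, rel=1e-10)

    def test_constant_regressor_raises(self):
        with pytest.raises(DegenerateRegressorError):
            fit_glm_single(np.arange(5.0), np.full(5, 2.0))


class TestOptimizeGlobalDelay:
    def test_self_signal_gives_zero_delay(self):
        b = smooth_builder()
        gs = b.values(0.0)
        delay, r2 = optimize_global_delay(b, gs, detrend_design=False)
        assert delay == pytest.approx(0.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_recovers_injected_shift(self):
        b = smooth_builder()
        gs = b.values(3.4)
        delay, _ = optimize_global_delay(b, gs)
        assert delay == pytest.approx(3.4, abs=0.05)

    def test_matches_exhaustive_grid_oracle(self):
        b = smooth_builder()
        rng = np.random.default_rng(0)
        gs = b.values(2.7) + 0.5 * rng.standard_normal(b.n_frames)
        spec = DelaySearchSpec(-5.0, 5.0, 0.1)
        delay, r2 = optimize_global_delay(b, gs, spec)
        best = (-np.inf, None)
        for d in spec.delays():  # brute force over all 101 delays
            x = _detrend_rows(b.values(d))[0]
            _, r2_d = fit_glm_single(gs, x)
            if r2_d > best[0]:
                best = (r2_d, d)
        assert delay == pytest.approx(best[1])
        assert r2 == pytest.approx(best[0])

    def test_out_of_range_delay_clamps_with_warning(self):
        # single transient bump: correlation decays monotonically with |shift|
        t = np.arange(0.0, 200.0, 0.1)
        bump = 40 + 5 * np.exp(-((t - 100.0) ** 2) / (2 * 8.0**2))
        b = RegressorBuilder(UniformSeries(bump, dt=0.1), 2.0, 50, t0=2.0)
        gs = b.values(20.0)
        with pytest.warns(DelayRangeWarning):
            delay, _ = optimize_global_delay(b, gs, DelaySearchSpec(-15, 15, 0.1))
        assert abs(abs(delay) - 15.0) < 1e-9


class TestGlobOpt:
    def test_uniform_phantom_exact(self):
        b = smooth_builder()
        x = b.values(0.0)
        run = run_from_voxels([100 + 0.3 * (x - x.mean())] * 3)
        res = fit_globopt(run, b.at_delay(0.0), detrend_design=False)
        assert np.allclose(res.beta[res.mask], 0.3)
        assert np.allclose(res.r2[res.mask], 1.0)

    def test_two_voxel_betas_recovered(self):
        b = smooth_builder()
        x = b.values(0.0)
        xc = x - x.mean()
        run = run_from_voxels([100 + 0.1 * xc, 100 + 0.5 * xc])
        res = fit_globopt(run, b.at_delay(0.0), detrend_design=False)
        assert np.allclose(res.beta[:, 0, 0], [0.1, 0.5])

    def test_noisy_mean_beta_within_ten_percent(self):
        """Monte-Carlo over 200 voxels at roughly R2 ~ 0.4."""
        b = smooth_builder(n_frames=134)
        x = b.values(0.0)
        xc = x - x.mean()
        rng = np.random.default_rng(3)
        sigma = 0.3 * xc.std() * np.sqrt(0.6 / 0.4)  # signal/total var near 0.4
        voxels = 100 + 0.3 * xc + sigma * rng.standard_normal((200, xc.size))
        res = fit_globopt(run_from_voxels(list(voxels)), b.at_delay(0.0),
                          detrend_design=False)
        mean_beta = res.beta[res.mask].mean()
        assert abs(mean_beta - 0.3) / 0.3 < 0.1
        assert 0.2 < np.median(res.r2[res.mask]) < 0.6


class TestVoxOpt:
    def test_recovers_voxel_delay_and_amplitude(self):
        b = smooth_builder()
        x18 = b.values(1.8)
        run = run_from_voxels([100 + 0.25 * (x18 - x18.mean())] * 2)
        res = fit_voxopt(run, b, DelaySearchSpec(-5, 5, 0.1), global_delay=0.0)
        assert np.allclose(res.delay[res.mask], 1.8)
        assert np.allclose(res.beta[res.mask], 0.25, rtol=1e-6)

    def test_zero_offset_for_globally_aligned_voxel(self):
        b = smooth_builder()
        x = b.values(2.0)
        run = run_from_voxels([100 + 0.3 * (x - x.mean())])
        res = fit_voxopt(run, b, DelaySearchSpec(-5, 5, 0.1), global_delay=2.0)
        assert res.rel_delay[res.mask][0] == pytest.approx(0.0)

    def test_white_noise_voxel_reports_small_r2(self, rng):
        b = smooth_builder()
        run = run_from_voxels([100 + rng.standard_normal(b.n_frames)])
        res = fit_voxopt(run, b, DelaySearchSpec(-3, 3, 0.1), global_delay=0.0)
        assert res.r2[res.mask][0] < 0.3

    def test_dominates_globopt_everywhere(self, noisy_study):
        st = noisy_study
        brain = st.truth.brain
        assert np.all(st.voxopt.r2[brain] >= st.globopt.r2[brain] - 1e-10)

    def test_unit_scaling_inverse_in_beta(self):
        """Scaling the CO2 regressor by k divides every beta by k."""
        b = smooth_builder()
        x = b.values(0.0)
        run = run_from_voxels([100 + 0.3 * (x - x.mean())] * 2)
        scaled = RegressorBuilder(
            UniformSeries(3.0 * b.series.values, dt=0.1), b.tr, b.n_frames, b.t0
        )
        res1 = fit_voxopt(run, b, DelaySearchSpec(-2, 2, 0.1), global_delay=0.0)
        res3 = fit_voxopt(run, scaled, DelaySearchSpec(-2, 2, 0.1), global_delay=0.0)
        assert np.allclose(res3.beta[res3.mask], res1.beta[res1.mask] / 3.0)

    def test_noiseless_phantom_delays_exact(self, noiseless_study):
        st = noiseless_study
        err = np.abs(st.voxopt.delay - st.truth.delay_map)[st.truth.brain]
        assert err.max() <= 0.1 + 1e-9

    def test_noisy_phantom_median_delay_error(self, noisy_study):
        """At voxel R2 near 0.4, median |delay error| stays within 0.5 s."""
        st = noisy_study
        brain = st.truth.brain
        assert brain.sum() >= 500
        err = np.abs(st.voxopt.delay - st.truth.delay_map)[brain]
        assert np.median(err) <= 0.5


class TestRHsig:
    def test_reference_voxel_scores_100(self):
        rng = np.random.default_rng(0)
        fluct = np.sin(np.arange(40.0)) + 0.1 * rng.standard_normal(40)
        run = run_from_voxels([100 + fluct, 100 + fluct, 100 + 0.5 * fluct])
        ref = np.zeros((3, 1, 1), bool)
        ref[:2] = True
        res = fit_rhsig(run, ref)
        assert res.beta[0, 0, 0] == pytest.approx(100.0)
        assert res.beta[2, 0, 0] == pytest.approx(50.0)

    def test_heterogeneous_reference_matches_bruteforce_oracle(self):
        b = smooth_builder()
        series = [b.values(d) for d in (0.0, 0.8, 1.6, -0.8)]
        voxels = [100 + 0.3 * (s - s.mean()) for s in series]
        run = run_from_voxels(voxels)
        ref = np.ones((4, 1, 1), bool)
        res = fit_rhsig(run, ref)
        mean_series = np.mean(voxels, axis=0)  # brute-force mask mean
        x = mean_series - 100.0
        for v, vox in enumerate(voxels):
            beta, _ = fit_glm_single(vox, x)
            assert res.beta[v, 0, 0] == pytest.approx(100 * beta, rel=1e-9)

    def test_empty_reference_raises(self):
        run = run_from_voxels([100 + np.sin(np.arange(12.0))])
        with pytest.raises(ValueError):
            RHsigCvr().fit(run, np.zeros((1, 1, 1), bool))

    def test_reference_mask_self_mean_is_100_on_phantom(self, noiseless_study):
        st = noiseless_study
        r_hemi = st.truth.masks.r_hemi
        assert st.rhsig.beta[r_hemi].mean() == pytest.approx(100.0, abs=0.5)
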