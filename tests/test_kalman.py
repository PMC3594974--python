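"""Kalman filter: initialization, batch equivalence, covariance behavior."""

import numpy as np
import pytest

from odfstar import csa_transform as ct
from odfstar import kalman, simulate
from odfstar.config import ReconConfig
from odfstar.sh_ops import design_matrix


class TestInitState:
    def test_diagonal_prior_without_regularization(self, model4):
        st = kalman.init_state(model4, np.zeros(15), 4.0 * np.eye(15), 0.0)
        np.testing.assert_allclose(st.P, 4.0 * np.eye(15), atol=1e-12)

    def test_identity_prior_with_unit_lambda(self, model4):
        st = kalman.init_state(model4, np.zeros(15), np.eye(15), 1.0)
        expected = np.diag(1.0 / (1.0 + model4.reg_diag))
        np.testing.assert_allclose(st.P, expected, atol=1e-12)

    def test_zero_prior_mean_first_innovation_is_measurement(self, model4, design200):
        st = kalman.init_state(model4, np.zeros(15), 1e4 * np.eye(15), 0.006)
        _, gamma, _ = kalman.update(st, design200[0], 0.37, 0.01)
        assert gamma == pytest.approx(0.37)

    def test_non_pd_prior_rejected(self, model4):
        with pytest.raises(ValueError):
            kalman.init_state(model4, np.zeros(15), -np.eye(15), 0.0)


class TestUpdate:
    def test_uninformative_measurement_leaves_estimate(self, model4, design200):
        st = kalman.init_state(model4, np.ones(15), np.eye(15), 0.0)
        st2, _, _ = kalman.update(st, design200[0], 5.0, 1e12)
        np.testing.assert_allclose(st2.c, st.c, atol=1e-9)

    def test_invalid_sigma_rejected(self, model4, design200):
        st = kalman.init_state(model4, np.zeros(15), np.eye(15), 0.0)
        with pytest.raises(ValueError):
            kalman.update(st, design200[0], 0.0, 0.0)

    def test_recursive_least_squares_equivalence(self, model4, design200):
        # constant sigma2, lambda=0, diffuse prior -> ordinary least squares
        rng = np.random.default_rng(2)
        N = 40
        B = design200[:N]
        y = rng.normal(size=N)
        st = kalman.init_state(model4, np.zeros(15), 1e8 * np.eye(15), 0.0)
        for k in range(N):
            st, _, _ = kalman.update(st, B[k], y[k], 1.0)
        c_ols = np.linalg.lstsq(B, y, rcond=None)[0]
        np.testing.assert_allclose(st.c, c_ols, atol=1e-7)

    def test_heteroscedastic_batch_equivalence(self, model4, design200):
        # the module's headline invariant at the default diffuse prior
        rng = np.random.default_rng(3)
        y = rng.normal(size=200)
        sigma2 = 0.005 + 0.03 * rng.random(200)
        lam = 0.006
        cfg = ReconConfig()
        st = kalman.init_state(model4, np.zeros(15), cfg.prior_var * np.eye(15), lam)
        for k in range(200):
            st, _, _ = kalman.update(st, design200[k], y[k], sigma2[k])
        ts = ct.TransformedSignal(y=y, sigma2=sigma2, clip_mask=np.zeros(200, bool))
        c_batch = ct.batch_fit(ts, design200, model4, lam)
        rel = np.linalg.norm(st.c - c_batch) / np.linalg.norm(c_batch)
        assert rel < 1e-6

    def test_final_estimate_order_invariant(self, model4, design200):
        rng = np.random.default_rng(4)
        y = rng.normal(size=100)
        sigma2 = 0.01 + 0.02 * rng.random(100)
        perm = rng.permutation(100)

        def run(order):
            st = kalman.init_state(model4, np.zeros(15), 1e4 * np.eye(15), 0.006)
            for k in order:
                st, _, _ = kalman.update(st, design200[k], y[k], sigma2[k])
            return st.c

        c_fwd = run(np.arange(100))
        c_perm = run(perm)
        assert np.linalg.norm(c_fwd - c_perm) / np.linalg.norm(c_fwd) < 1e-6

    def test_covariance_trace_non_increasing(self, model4, design200):
        st = kalman.init_state(model4, np.zeros(15), np.eye(15), 0.006)
        traces = [np.trace(st.P)]
        for k in range(50):
            st, _, _ = kalman.update(st, design200[k], 0.1, 0.02)
            traces.append(np.trace(st.P))
        assert np.all(np.diff(traces) <= 1e-12)

    def test_covariance_stays_psd(self, model4, design200):
        st = kalman.init_state(model4, np.zeros(15), 1e4 * np.eye(15), 0.006)
        for k in range(100):
            st, _, _ = kalman.update(st, design200[k], 0.5, 0.01)
            assert np.min(np.linalg.eigvalsh(st.P)) > -1e-10


class TestExpectedOdfMse:
    def test_zero_covariance_gives_zero(self, model4):
        st = kalman.KalmanState(c=np.zeros(15), P=np.zeros((15, 15)), k=0, lambda_reg=0.0)
        assert kalman.expected_odf_mse(st, model4) == 0.0

    def test_identity_covariance_matches_brute_force(self, model4):
        st = kalman.KalmanState(c=np.zeros(15), P=np.eye(15), k=0, lambda_reg=0.0)
        scale = ct.odf_scale_vector(model4)
        brute = sum(scale[j] ** 2 for j in range(15))
        assert kalman.expected_odf_mse(st, model4) == pytest.approx(brute, rel=1e-12)

    def test_mse_decreases_with_more_measurements(self, model4, tiny_phantom, tiny_scheme):
        acq = simulate.synthesize_dwi(tiny_phantom, tiny_scheme, snr=20.0, seed=5)
        cfg = ReconConfig(n_monitor=50, noise_var=acq.noise_sigma**2, seed=5)
        res = kalman.run_volume_stream(
            (acq.data[..., v] for v in range(tiny_scheme.n_volumes)),
            tiny_scheme,
            tiny_phantom.mask,
            config=cfg,
            reconstruct_all=False,
        )
        assert res.mse_trace[29] < res.mse_trace[14]
        assert np.all(res.mse_trace > 0)


class TestVolumeStream:
    def test_single_voxel_matches_direct_updates(self, model4, tiny_phantom, tiny_scheme):
        acq = simulate.synthesize_dwi(tiny_phantom, tiny_scheme, snr=20.0, seed=8)
        cfg = ReconConfig(noise_var=acq.noise_sigma**2, seed=8)
        mask = np.zeros(tiny_phantom.shape, dtype=bool)
        center = tuple(s // 2 for s in tiny_phantom.shape)
        mask[center] = True
        res = kalman.run_volume_stream(
            (acq.data[..., v] for v in range(tiny_scheme.n_volumes)),
            tiny_scheme,
            mask,
            config=cfg,
            monitor_voxels=[0],
        )
        # replay manually with scalar updates
        is_b0 = tiny_scheme.b0_mask()
        s_series = acq.data[center]
        s0 = s_series[is_b0].mean()
        B = design_matrix(model4, tiny_scheme.dwi_directions())
        st = kalman.init_state(
            model4, np.zeros(15), cfg.prior_var * np.eye(15), cfg.lambda_reg
        )
        for k, s in enumerate(s_series[~is_b0]):
            e = np.clip(s / s0, cfg.clip_eps, 1 - cfg.clip_eps)
            y = np.log(-np.log(e))
            sig2 = cfg.noise_var / (s0 * e) ** 2 / np.log(e) ** 2
            st, gamma, V = kalman.update(st, B[k], y, sig2)
            assert gamma == pytest.approx(res.history.gamma[k, 0], rel=1e-9, abs=1e-12)
            assert V == pytest.approx(res.history.V[k, 0], rel=1e-9)
        np.testing.assert_allclose(res.signal_coeffs[center], st.c, rtol=1e-8)

    def test_monitored_record_count(self, tiny_phantom, tiny_scheme):
        acq = simulate.synthesize_dwi(tiny_phantom, tiny_scheme, snr=20.0, seed=9)
        cfg = ReconConfig(n_monitor=37, noise_var=acq.noise_sigma**2, seed=9)
        res = kalman.run_volume_stream(
            (acq.data[..., v] for v in range(tiny_scheme.n_volumes)),
            tiny_scheme,
            tiny_phantom.mask,
            config=cfg,
            reconstruct_all=False,
        )
        records = list(res.history.records())
        assert len(records) == 32
        assert all(r.gamma.shape == (37,) for r in records)
        assert all(np.all(r.V > 0) for r in records)

    def test_shape_mismatch_rejected(self, tiny_phantom, tiny_scheme):
        bad = [np.zeros((3, 3, 3))]
        with pytest.raises(ValueError, match="shape"):
            kalman.run_volume_stream(bad, tiny_scheme, tiny_phantom.mask)

    def test_volume_count_mismatch_rejected(self, tiny_phantom, tiny_scheme):
        acq = simulate.synthesize_dwi(tiny_phantom, tiny_scheme, snr=np.inf, seed=0)
        vols = [acq.data[..., v] for v in range(10)]
        with pytest.raises(ValueError, match="stream"):
            kalman.run_volume_stream(
                vols, tiny_scheme, tiny_phantom.mask,
                config=ReconConfig(noise_var=1e-4),
            )

    def test_null_innovations_standardized(self, tiny_phantom, tiny_scheme):
        """Pooled gamma/sqrt(V) is near standard normal without motion."""
        from odfstar.evaluate import population_prior

        prior = population_prior(tiny_phantom, tiny_scheme)
        pooled = []
        for seed in (21, 22):
            acq = simulate.synthesize_dwi(tiny_phantom, tiny_scheme, snr=20.0, seed=seed)
            cfg = ReconConfig(n_monitor=80, noise_var=acq.noise_sigma**2, seed=seed)
            res = kalman.run_volume_stream(
                (acq.data[..., v] for v in range(tiny_scheme.n_volumes)),
                tiny_scheme,
                tiny_phantom.mask,
                config=cfg,
                reconstruct_all=False,
                prior_mean=prior[0],
                prior_cov=prior[1],
            )
            pooled.append((res.history.gamma / np.sqrt(res.history.V)).ravel())
        u = np.concatenate(pooled)
        assert abs(u.mean()) < 3.0 / np.sqrt(u.size)
        assert 0.9 < u.var() < 1.1

    def test_innovation_whiteness_lag1(self, model4, design200):
        # 200-step scalar-noise null: innovations are serially uncorrelated
        rng = np.random.default_rng(31)
        c_true = rng.normal(size=15) * 0.3
        st = kalman.init_state(model4, np.zeros(15), 1e4 * np.eye(15), 0.0)
        u = []
        for k in range(200):
            y = design200[k] @ c_true + rng.normal(scale=0.1)
            st, gamma, V = kalman.update(st, design200[k], y, 0.01)
            u.append(gamma / np.sqrt(V))
        u = np.array(u[15:])  # identifiable regime
        r1 = np.corrcoef(u[:-1], u[1:])[0, 1]
        assert abs(r1) < 0.1
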