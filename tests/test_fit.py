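import numpy as np
import pytest

from modmindy import (
    FitConfig,
    LabeledRecording,
    ModulationMatrix,
    SynthConfig,
    apply_constraints,
    fit,
    free_sim_predict,
    generate_dataset,
    kalman_filter_window,
    masked_correlation,
    random_init,
    simulate,
)
from conftest import make_toy_params, oracle_step


def textbook_kalman_filter(A, b, H, Q, R, y, x0, P0):
    """Independent linear Kalman filter: x' = A x + b, y = H x."""
    x, P = x0.copy(), P0.copy()
    xs = []
    for t in range(y.shape[1]):
        x = A @ x + b
        P = A @ P @ A.T + Q
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        x = x + K @ (y[:, t] - H @ x)
        P = (np.eye(x.size) - K @ H) @ P
        xs.append(x.copy())
    return np.array(xs).T


class TestKalmanWindow:
    def test_linear_regime_matches_textbook_kalman_filter(self):
        """With W = 0 the dynamics are exactly linear (x' = (I-D)x + C), so
        the extended filter must coincide with a textbook linear KF."""
        p = make_toy_params(d=0.4)
        p.W.Wee[:] = 0
        p.W.Wie[:] = 0
        p.W.Wei[:] = 0
        p.W.Wii[:] = 0
        p.C = np.array([0.2, -0.1])
        p.Q = 0.3 * np.eye(2)
        p.R = 0.5 * np.eye(1)
        rng = np.random.default_rng(0)
        y = rng.normal(size=(1, 40))
        labels = np.ones(40, dtype=int)
        xs, _, _ = kalman_filter_window(p, y, labels, x0=np.zeros(2),
                                        P0=np.eye(2))
        A = np.eye(2) - np.diag(p.D)
        want = textbook_kalman_filter(A, p.C, p.H, p.Q, p.R, y,
                                      np.zeros(2), np.eye(2))
        assert np.max(np.abs(xs - want)) < 1e-10

    def test_noiseless_observability_drives_innovations_to_zero(self):
        """Square full-rank excitatory lead field and tiny measurement
        noise: the filter locks onto the observed excitatory states and
        late innovations are far smaller than early ones."""
        cfg = SynthConfig(n_exc=4, n_inh=4, T=300, meas_noise_base=0.0,
                          meas_noise_jitter=0.0)
        b = generate_dataset(cfg, seed=2)
        p = b.params.copy()
        p.R = 1e-12 * np.eye(p.n_channels)
        xs, _, _ = kalman_filter_window(p, b.recording.y[:, :200],
                                        b.labels[:200])
        early = np.abs(b.recording.y[:, 1] - p.H @ xs[:, 0]).max()
        resid = [np.abs(b.recording.y[:, t] - p.H @ xs[:, t]).max()
                 for t in range(150, 199)]
        assert np.median(resid) < 1e-3 * max(early, 1.0)

    def test_all_ones_modulations_make_regime_switches_invisible(self):
        p = make_toy_params(m=2)
        p.gammas = [ModulationMatrix.ones(1, 2), ModulationMatrix.ones(2, 2)]
        p.Q = 0.1 * np.eye(2)
        p.R = 0.1 * np.eye(1)
        rng = np.random.default_rng(1)
        y = rng.normal(size=(1, 30))
        switching = np.array([1] * 15 + [2] * 15)
        xs1, _, e1 = kalman_filter_window(p, y, switching)
        xs2, _, e2 = kalman_filter_window(p, y, np.ones(30, dtype=int))
        assert np.array_equal(xs1, xs2)
        assert e1 == e2


class TestFreeSim:
    def test_three_step_prediction_matches_chained_oracle(self):
        p = make_toy_params()
        x = np.array([0.1, -0.2])
        preds, _ = free_sim_predict(p, x, [1, 1, 1])
        xo = x.copy()
        for k in range(3):
            xo = oracle_step(xo, p, 1)
            assert np.max(np.abs(preds[:, k] - p.H @ xo)) < 1e-12

    def test_matches_noise_free_simulate(self, small_bundle):
        p = small_bundle.params.copy()
        p.Q = np.zeros_like(p.Q)
        p.R = np.zeros_like(p.R)
        x0 = np.full(p.n, 0.3)
        labels = small_bundle.labels[:20]
        states, obs = simulate(p, labels, x0=x0, seed=0)
        # rollout from the state at t=1 predicts the observations at t=2..
        preds, _ = free_sim_predict(p, states[:, 1], labels[1:-1])
        assert np.allclose(preds, obs[:, 2:], atol=1e-12, rtol=0), \
            "rollout and generative simulation must share the same dynamics"

    def test_perfect_model_zero_error_on_horizon_one(self):
        p = make_toy_params()
        x = np.array([0.4, -0.1])
        x_next = oracle_step(x, p, 1)
        y_next = (p.H @ x_next).reshape(-1, 1)
        _, err = free_sim_predict(p, x, [1], horizon=1, y_future=y_next)
        assert err < 1e-20


class TestApplyConstraints:
    def test_idempotent_on_feasible_params(self, small_bundle):
        p = small_bundle.params
        q = apply_constraints(p)
        for blk in ("Wee", "Wie", "Wei", "Wii"):
            assert np.array_equal(getattr(q.W, blk), getattr(p.W, blk))
        for gp, gq in zip(p.gammas, q.gammas):
            assert np.array_equal(gp.u, gq.u) and np.array_equal(gp.v, gq.v)

    def test_single_negative_entry_clamped_locally(self, small_bundle):
        p = small_bundle.params.copy()
        i, j = 0, 1
        if not p.W.mask_ee[i, j]:
            p.W.mask_ee[i, j] = True
        p.W.Wee[i, j] = -0.7
        q = apply_constraints(p)
        assert q.W.Wee[i, j] == 0.0
        others = np.ones_like(p.W.Wee, dtype=bool)
        others[i, j] = False
        assert np.array_equal(q.W.Wee[others], p.W.Wee[others])

    def test_random_infeasible_params_match_elementwise_clamp_oracle(self,
                                                                     small_bundle):
        rng = np.random.default_rng(5)
        p = small_bundle.params.copy()
        p.W.Wee += rng.normal(scale=2.0, size=p.W.Wee.shape)
        p.W.Wei += rng.normal(scale=2.0, size=p.W.Wei.shape)
        p.W.Wie = np.diag(rng.normal(scale=2.0, size=p.n_exc))
        p.W.Wii = np.diag(rng.normal(scale=2.0, size=p.n_inh))
        for g in p.gammas:
            g.u = rng.normal(size=g.u.shape)
            g.v = rng.normal(size=g.v.shape)
        q = apply_constraints(p)
        q.validate()
        # brute-force elementwise clamp oracle
        want_ee = np.maximum(p.W.Wee, 0)
        want_ee[~p.W.mask_ee] = 0
        assert np.array_equal(q.W.Wee, want_ee)
        want_ie = np.diag(np.minimum(np.diag(p.W.Wie), 0))
        assert np.array_equal(q.W.Wie, want_ie)
        for gp, gq in zip(p.gammas, q.gammas):
            assert np.array_equal(gq.u, np.maximum(gp.u, 0))

    def test_pinned_baseline_reset_to_ones(self, small_bundle):
        p = small_bundle.params.copy()
        p.gammas[0].u += 0.5
        q = apply_constraints(p, pin_gamma1=True)
        assert np.array_equal(q.gammas[0].dense(),
                              np.ones((p.n, p.n)))


def _quick_fit_config(**kw):
    base = dict(kalman_window_len=60, free_sim_horizon=10, kalman_burn_in=5,
                learning_rate=0.02, max_iterations=120, convergence_tol=1e-9,
                n_windows_per_epoch=30, seed=7)
    base.update(kw)
    return FitConfig(**base)


class TestFit:
    def test_low_noise_self_recovery(self):
        """Fitting data generated by a known small model (true lead field
        and noise covariances supplied, true sparsity mask shared) recovers
        the excitatory connectivity."""
        cfg = SynthConfig(n_exc=4, n_inh=4, m=2, T=2000)
        b = generate_dataset(cfg, seed=23)
        p = b.params
        init = random_init(4, 4, 2, p.H, p.Q, p.R, mask_ee=p.W.mask_ee,
                           mask_ei=p.W.mask_ei, seed=99)
        fcfg = FitConfig(kalman_window_len=400, free_sim_horizon=25,
                         learning_rate=0.035, max_iterations=250,
                         convergence_tol=1e-9, seed=5, full_batch_frac=1.0,
                         weight_decay=0.03, holdout_frac=0.15,
                         holdout_patience=4, n_windows_per_epoch=25,
                         tail_average_frac=0.0)
        res = fit(b.recording, fcfg, init=init)
        rep = masked_correlation(p, res.params)
        assert rep.r_Wee > 0.9
        assert rep.r_full_W > 0.85

    def test_smoothed_error_decreases_substantially(self):
        cfg = SynthConfig(n_exc=4, n_inh=4, m=2, T=2000,
                          process_noise_var=0.01,
                          meas_noise_base=0.01, meas_noise_jitter=0.0)
        b = generate_dataset(cfg, seed=21)
        p = b.params
        init = random_init(4, 4, 2, p.H, p.Q, p.R, mask_ee=p.W.mask_ee,
                           mask_ei=p.W.mask_ei, seed=99)
        fcfg = FitConfig(kalman_window_len=400, free_sim_horizon=25,
                         learning_rate=0.035, max_iterations=150,
                         convergence_tol=1e-9, seed=5, full_batch_frac=1.0,
                         n_windows_per_epoch=1000, tail_average_frac=0.0)
        res = fit(b.recording, fcfg, init=init)
        tot = res.loss_trace.sum(axis=1)
        first = tot[:10].mean()
        last = tot[-10:].mean()
        assert last < first / 10

    def test_pinned_gamma1_survives_optimization(self, small_bundle):
        rec = small_bundle.recording
        cfg = _quick_fit_config(pin_gamma1=True)
        init = random_init(4, 4, 2, small_bundle.params.H,
                           small_bundle.params.Q, small_bundle.params.R,
                           seed=3, pin_gamma1=True)
        res = fit(rec, cfg, init=init)
        g1 = res.params.gammas[0]
        assert np.array_equal(g1.u, np.ones(8))
        assert np.array_equal(g1.v, np.ones(8))

    def test_same_seed_reproducible(self, small_bundle):
        rec = small_bundle.recording
        p = small_bundle.params
        for trial in range(2):
            init = random_init(4, 4, 2, p.H, p.Q, p.R, seed=3)
            res = fit(rec, _quick_fit_config(), init=init)
            if trial == 0:
                ref = res.params
        assert np.array_equal(ref.W.assemble(), res.params.W.assemble())
        assert np.array_equal(ref.D, res.params.D)

    def test_every_iterate_is_feasible(self, small_bundle):
        res = fit(small_bundle.recording, _quick_fit_config(),
                  init=random_init(4, 4, 2, small_bundle.params.H,
                                   small_bundle.params.Q,
                                   small_bundle.params.R, seed=3))
        res.params.validate()

    def test_label_coverage_validated(self, small_bundle):
        rec = small_bundle.recording
        bad = LabeledRecording(y=rec.y, fs=rec.fs,
                               labels=np.ones(rec.T, dtype=int))
        init = random_init(4, 4, 2, small_bundle.params.H,
                           small_bundle.params.Q, small_bundle.params.R,
                           seed=3)
        with pytest.raises(ValueError):
            fit(bad, _quick_fit_config(), init=init)


class TestGradientCorrectness:
    def test_full_backward_matches_finite_differences(self, small_bundle):
        """The hand-derived reverse-mode gradient (covariance recursion
        included) agrees with central finite differences of the actual
        window loss, spot-checked on entries of every parameter group."""
        from modmindy.fit import (_assemble_theta, _backward_window,
                                  _ekf_forward, _factor_gamma_grads,
                                  _rollout_forward, _theta_from_params,
                                  _zero_grads)
        p = small_bundle.params
        y = small_bundle.recording.y
        labels = small_bundle.labels
        ne = ni = 4
        n = 8
        L, h, burn = 10, 4, 2
        sl_k, sl_f = slice(5, 5 + L), slice(5 + L, 5 + L + h)
        x0, P0 = np.zeros(n), np.eye(n)
        th0 = _theta_from_params(p, FitConfig())

        def loss(th):
            W, gam, Ms, svec = _assemble_theta(th, ne, ni)
            xs, _, ke, kc = _ekf_forward(
                y[:, sl_k], labels[sl_k], x0, P0, Ms, svec, th["d"],
                th["voff"], th["c"], th["H"], np.exp(th["log_q"]),
                np.exp(th["log_r"]), burn_in=burn)
            _, _, fe, rc = _rollout_forward(
                xs[:, -1], labels[sl_f], Ms, svec, th["d"], th["voff"],
                th["c"], th["H"], y[:, sl_f])
            return ke + fe, kc, rc

        _, kc, rc = loss(th0)
        grads = _zero_grads(th0)
        W, gam, Ms, svec = _assemble_theta(th0, ne, ni)
        _backward_window(th0, grads, W, gam, Ms, svec, th0["H"], kc, rc,
                         y[:, sl_k], y[:, sl_f], burn, True, True, ne,
                         full_cov=True)
        _factor_gamma_grads(th0, grads)

        rng = np.random.default_rng(0)
        eps = 1e-6
        for key in ("Wee", "Wei", "wie", "wii", "U", "Vg", "d", "s_exc",
                    "voff", "c", "H", "log_q", "log_r"):
            arr = np.asarray(th0[key], float)
            flat_idx = (rng.choice(arr.size, size=min(3, arr.size),
                                   replace=False) if arr.ndim else [None])
            for fi in flat_idx:
                thp = {k: np.array(v, float, copy=True) for k, v in th0.items()}
                thm = {k: np.array(v, float, copy=True) for k, v in th0.items()}
                if fi is None:
                    thp[key] = arr + eps
                    thm[key] = arr - eps
                    ga = float(np.asarray(grads[key]))
                else:
                    thp[key].flat[fi] += eps
                    thm[key].flat[fi] -= eps
                    ga = np.asarray(grads[key]).flat[fi]
                gnum = (loss(thp)[0] - loss(thm)[0]) / (2 * eps)
                assert ga == pytest.approx(gnum, abs=1e-4 + 1e-5 * abs(gnum)), key
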