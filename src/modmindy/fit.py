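"""Dual estimation: extended Kalman filtering + free-simulation forecasting
with backpropagated gradient updates under structural constraints.

The fitting loop repeatedly (i) draws a random window of the recording,
(ii) runs an extended Kalman filter (EKF) over the window to estimate the
latent E/I population states, (iii) rolls the model forward noiselessly
from the last filtered state over a short horizon ("free simulation"),
(iv) backpropagates the summed innovation and multi-step prediction errors
into every learnable parameter, (v) takes a NADAM step, and (vi) projects
the parameters back onto the constraint set (signs, diagonality, sparsity
mask, rank-1 nonnegative modulation factors, pinned baseline modulation,
floored noise covariances).  Iteration stops when an exponentially
smoothed combined error stops improving.

Gradients are computed by hand-written reverse-mode accumulation:

* the free-simulation rollout is differentiated exactly (full
  backpropagation through time);
* the Kalman phase is differentiated through the filter *mean* recursion
  ``x_filt = (I - K H) f(x_filt_prev) + K y`` with the gains and
  covariances treated as constants of the backward pass (their own
  parameter sensitivity is dropped);
* the noise covariances receive the gradient of the per-step Gaussian
  innovation negative log-likelihood ``e' S^-1 e + log det S`` with the
  one-step-ahead state covariance held fixed, which pulls the learned
  ``Q``/``R`` diagonals toward innovation-consistent values.

Noise covariances are learned as diagonals through log-parameterization
with a floor at 1e-6, so they remain positive definite by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _k
from .model import (
    DECAY_SIGN,
    LabeledRecording,
    ModelParameters,
    ModulationMatrix,
    StructuredConnectivity,
    random_offdiag_mask,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "FitDivergenceError",
    "kalman_filter_window",
    "free_sim_predict",
    "apply_constraints",
    "random_init",
    "fit",
]

_LOG_FLOOR = np.log(1e-6)


class FitDivergenceError(RuntimeError):
    """Raised when the optimization diverges; carries the last stable params."""

    def __init__(self, message: str, last_params: ModelParameters | None = None):
        super().__init__(message)
        self.last_params = last_params


@dataclass
class FitConfig:
    """Hyperparameters of the dual-estimation loop.

    One iteration processes one randomly drawn window: ``kalman_window_len``
    filtered steps followed by ``free_sim_horizon`` free-simulation steps.
    The first ``kalman_burn_in`` innovations are excluded from the loss
    (the filter needs a few steps to lock on from its zero-state prior)
    but the filter itself runs from the start of the window.  Convergence
    is declared when the exponentially smoothed combined error (half-life
    ``ema_half_life`` iterations) changes by less than ``convergence_tol``
    relative between consecutive checks, made every ``n_windows_per_epoch``
    iterations.
    """

    kalman_window_len: int = 200
    free_sim_horizon: int = 20
    kalman_burn_in: int = 10
    n_windows_per_epoch: int = 50
    learning_rate: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    max_iterations: int = 3000
    convergence_tol: float = 1e-4
    ema_half_life: float = 50.0
    seed: int = 0
    pin_gamma1: bool = False
    learn_H: bool = False
    learn_noise: bool = True
    noise_grad_scale: float = 1.0
    min_slope: float = 1e-3
    max_bad_iterations: int = 50
    batch_windows: int = 1
    lr_schedule: str = "cosine"  # "cosine" anneals to lr_min_frac, "constant"
    lr_min_frac: float = 0.02
    tail_average_frac: float = 0.25  # average params over this trailing fraction
    gauge_fix: bool = True  # normalize modulation factors' geometric mean to 1
    # final deterministic phase: the last fraction of iterations replaces the
    # random window draw with a fixed tiling of the whole recording, removing
    # window-sampling noise so that weakly determined directions (inhibitory
    # pathways, modulation spread) receive a coherent gradient
    full_batch_frac: float = 0.0
    # mild ridge on the connectivity blocks (per-iteration, scaled into the
    # gradient): tames the variance inflation of weakly determined entries
    # (notably the E->I block, whose states are never observed directly)
    weight_decay: float = 0.0
    # innovation loss weighting: "squared" sums ||e||^2; "whitened" sums
    # the Mahalanobis form e' S^-1 e (S treated as constant in the
    # backward pass), equalizing information across observation directions
    innovation_weighting: str = "squared"
    # include the covariance recursion (gains, innovation covariances) in
    # the backward pass; when off, the gains are treated as constants
    covariance_backprop: bool = True
    # temporal-holdout early stopping: reserve the trailing fraction of the
    # recording, score the (forward-only) innovation + free-simulation error
    # on it at every convergence check, and return the parameters from the
    # best check.  Guards against the late-phase drift in which near-flat
    # loss directions absorb noise idiosyncrasies of a finite recording.
    holdout_frac: float = 0.0
    holdout_patience: int = 6

    def __post_init__(self) -> None:
        if self.kalman_window_len < 1 or self.free_sim_horizon < 1:
            raise ValueError("window lengths must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if not 0 <= self.kalman_burn_in < self.kalman_window_len:
            raise ValueError("kalman_burn_in must be in [0, kalman_window_len)")


@dataclass
class FitResult:
    params: ModelParameters
    loss_trace: np.ndarray  # (iterations, 2): [kalman error, free-sim error]
    window_log: np.ndarray  # window start index per iteration
    converged: bool
    n_iterations: int = 0


# ---------------------------------------------------------------------------
# internal flat parameterization
# ---------------------------------------------------------------------------

def _theta_from_params(p: ModelParameters, cfg: FitConfig) -> dict:
    th = {
        "Wee": p.W.Wee.copy(),
        "Wei": p.W.Wei.copy(),
        "wie": np.diag(p.W.Wie).copy(),
        "wii": np.diag(p.W.Wii).copy(),
        "U": np.stack([g.u for g in p.gammas]).copy(),
        "Vg": np.stack([g.v for g in p.gammas]).copy(),
        "d": p.D.copy(),
        "s_exc": np.array(p.s_exc),
        "s_inh": np.array(p.s_inh),
        "voff": p.V.copy(),
        "c": p.C.copy(),
        "log_q": np.log(np.clip(np.diag(p.Q), 1e-6, None)),
        "log_r": np.log(np.clip(np.diag(p.R), 1e-6, None)),
        "H": p.H.copy(),
    }
    return th


def _params_from_theta(th: dict, template: ModelParameters,
                       cfg: FitConfig) -> ModelParameters:
    ne, ni = template.n_exc, template.n_inh
    W = StructuredConnectivity(
        ne, ni, th["Wee"].copy(), np.diag(th["wie"]), th["Wei"].copy(),
        np.diag(th["wii"]), template.W.mask_ee.copy(), template.W.mask_ei.copy(),
    )
    gammas = []
    for i in range(template.m):
        pinned = cfg.pin_gamma1 and i == 0
        gammas.append(ModulationMatrix(i + 1, th["U"][i].copy(), th["Vg"][i].copy(),
                                       pinned=pinned))
    return ModelParameters(
        W=W, gammas=gammas, D=th["d"].copy(),
        s_exc=float(th["s_exc"]), s_inh=float(th["s_inh"]),
        V=th["voff"].copy(), C=th["c"].copy(), H=th["H"].copy(),
        Q=np.diag(np.exp(th["log_q"])), R=np.diag(np.exp(th["log_r"])),
    )


def _project_theta(th: dict, mask_ee: np.ndarray, mask_ei: np.ndarray,
                   cfg: FitConfig) -> None:
    """In-place projection onto the constraint set (elementwise clamps)."""
    np.clip(th["Wee"], 0.0, None, out=th["Wee"])
    np.clip(th["Wei"], 0.0, None, out=th["Wei"])
    th["Wee"][~mask_ee] = 0.0
    th["Wei"][~mask_ei] = 0.0
    np.clip(th["wie"], None, 0.0, out=th["wie"])
    np.clip(th["wii"], None, 0.0, out=th["wii"])
    np.clip(th["U"], 0.0, None, out=th["U"])
    np.clip(th["Vg"], 0.0, None, out=th["Vg"])
    if cfg.pin_gamma1:
        th["U"][0] = 1.0
        th["Vg"][0] = 1.0
    elif cfg.gauge_fix:
        # W and {Gamma_i} are only identified up to a shared elementwise
        # rank-1 factor (W -> W o a b^T, u_i -> u_i/a, v_i -> v_i/b).  Fix
        # the gauge by normalizing the geometric mean of the factors across
        # regimes to 1, absorbing it into W; this anchors modulations near
        # their natural scale (values around 1) and stops slow gauge drift.
        gu = np.exp(np.mean(np.log(np.clip(th["U"], 1e-3, None)), axis=0))
        gv = np.exp(np.mean(np.log(np.clip(th["Vg"], 1e-3, None)), axis=0))
        th["U"] /= gu[None, :]
        th["Vg"] /= gv[None, :]
        ne_loc = th["Wee"].shape[0]
        th["Wee"] *= np.outer(gu[:ne_loc], gv[:ne_loc])
        th["Wei"] *= np.outer(gu[ne_loc:], gv[:ne_loc])
        th["wie"] *= gu[:ne_loc] * gv[ne_loc:]
        th["wii"] *= gu[ne_loc:] * gv[ne_loc:]
    np.clip(th["d"], 0.0, None, out=th["d"])
    th["s_exc"] = np.maximum(th["s_exc"], cfg.min_slope)
    th["s_inh"] = np.maximum(th["s_inh"], cfg.min_slope)
    np.clip(th["log_q"], _LOG_FLOOR, None, out=th["log_q"])
    np.clip(th["log_r"], _LOG_FLOOR, None, out=th["log_r"])


def _assemble_theta(th: dict, ne: int, ni: int):
    """Dense W, per-regime effective matrices M_i = W o Gamma_i, slope vector."""
    n = ne + ni
    W = np.zeros((n, n))
    W[:ne, :ne] = th["Wee"]
    W[:ne, ne:] = np.diag(th["wie"])
    W[ne:, :ne] = th["Wei"]
    W[ne:, ne:] = np.diag(th["wii"])
    gam = np.stack([np.outer(th["U"][i], th["Vg"][i])
                    for i in range(th["U"].shape[0])])
    Ms = W[None, :, :] * gam
    svec = np.concatenate([np.full(ne, float(th["s_exc"])),
                           np.full(ni, float(th["s_inh"]))])
    return W, gam, Ms, svec


def _zero_grads(th: dict) -> dict:
    g = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in th.items()}
    # gamma gradients are accumulated densely first, then factored
    g["_Gam"] = np.zeros((th["U"].shape[0], th["U"].shape[1], th["Vg"].shape[1]))
    return g


# ---------------------------------------------------------------------------
# forward passes with caches
# ---------------------------------------------------------------------------

def _ekf_forward(y: np.ndarray, labels: np.ndarray, x0: np.ndarray,
                 P0: np.ndarray, Ms, svec, d, voff, c, H, Qd, Rd,
                 burn_in: int = 0, fixed_gains=None, whiten: bool = False):
    """EKF forward pass.  Returns filtered means, final covariance, summed
    innovation error (post burn-in), and the caches needed for backprop.

    ``fixed_gains`` (array of K_t) replays a frozen gain sequence; used to
    validate the backward pass against finite differences.
    """
    y = np.ascontiguousarray(y, dtype=float)
    labels = np.ascontiguousarray(labels, dtype=np.int64)
    n = x0.size
    nc = y.shape[0]
    if fixed_gains is None:
        Kfix = np.zeros((1, n, nc))
        use_fixed = False
    else:
        Kfix = np.ascontiguousarray(fixed_gains, dtype=float)
        use_fixed = True
    (xs, P, err, x_prev, phi_c, x_pred_c, e_c, K_c, Sinv_c, Pf_c, Pp_c,
     bad_t) = \
        _k.ekf_forward(y, labels, np.ascontiguousarray(x0, dtype=float),
                       np.ascontiguousarray(P0, dtype=float),
                       np.ascontiguousarray(Ms, dtype=float),
                       svec, d, voff, c,
                       np.ascontiguousarray(H, dtype=float), Qd, Rd,
                       burn_in, DECAY_SIGN, Kfix, use_fixed, whiten)
    if bad_t >= 0:
        raise FitDivergenceError(f"EKF state diverged at window step {bad_t}")
    cache = {"x_prev": x_prev, "phi": phi_c, "x_pred": x_pred_c, "e": e_c,
             "K": K_c, "Sinv": Sinv_c, "Pf": Pf_c, "Pp": Pp_c,
             "x0": np.asarray(x0, dtype=float),
             "P0": np.asarray(P0, dtype=float), "regime": labels}
    return xs, P, float(err), cache


def _rollout_forward(x_start: np.ndarray, labels_fut: np.ndarray, Ms, svec, d,
                     voff, c, H, y_fut: np.ndarray | None):
    """Noiseless rollout; returns states after each step, predicted
    observations, squared error vs y_fut (0.0 when y_fut is None), and
    caches."""
    labels_fut = np.ascontiguousarray(labels_fut, dtype=np.int64)
    H = np.ascontiguousarray(H, dtype=float)
    nc = H.shape[0]
    score = y_fut is not None
    if y_fut is None:
        y_fut = np.zeros((nc, labels_fut.size))
    states, err, x_prev, phi_c, bad_k = _k.rollout_forward(
        np.ascontiguousarray(x_start, dtype=float), labels_fut,
        np.ascontiguousarray(Ms, dtype=float), svec, d, voff, c, H,
        np.ascontiguousarray(y_fut, dtype=float), DECAY_SIGN)
    if bad_k >= 0:
        raise FitDivergenceError(f"free simulation diverged at step {bad_k}")
    cache = {"x_prev": x_prev, "phi": phi_c, "states": states,
             "regime": labels_fut}
    preds = H @ states
    return states, preds, (float(err) if score else 0.0), cache


# ---------------------------------------------------------------------------
# backward accumulation
# ---------------------------------------------------------------------------

def _backward_window(th, grads, W, gam, Ms, svec, H, kf_cache, roll_cache,
                     y_win, y_fut, burn_in: int, learn_H: bool,
                     learn_noise: bool, ne: int,
                     whiten: bool = False, full_cov: bool = False) -> None:
    """Backpropagate the combined error of one window into ``grads``.

    The free-simulation segment is differentiated exactly (BPTT); the
    Kalman segment is differentiated through the filter mean recursion
    with the gains frozen; the noise diagonals receive the one-step
    innovation-NLL gradient.
    """
    n = th["d"].size
    gW = np.zeros((n, n))
    gd = np.zeros(n)
    gsvec = np.zeros(n)
    gvoff = np.zeros(n)
    gc = np.zeros(n)
    gH = np.zeros_like(np.asarray(th["H"], dtype=float))
    Qd = np.exp(th["log_q"])
    Rd = np.exp(th["log_r"])
    gq = np.zeros_like(Qd)
    gr = np.zeros_like(Rd)
    if full_cov:
        _k.backward_window_full(
            kf_cache["regime"], kf_cache["x_prev"], kf_cache["phi"],
            kf_cache["x_pred"], kf_cache["e"], kf_cache["K"],
            kf_cache["Sinv"], kf_cache["Pf"], kf_cache["Pp"],
            kf_cache["x0"], kf_cache["P0"],
            roll_cache["regime"], roll_cache["x_prev"], roll_cache["phi"],
            roll_cache["states"],
            np.ascontiguousarray(y_fut, dtype=float),
            np.ascontiguousarray(Ms, dtype=float),
            np.ascontiguousarray(gam, dtype=float),
            np.ascontiguousarray(W, dtype=float),
            svec, th["d"], th["c"], np.ascontiguousarray(H, dtype=float),
            Qd, Rd, burn_in, DECAY_SIGN, learn_H,
            gW, grads["_Gam"], gd, gsvec, gvoff, gc, gH, gq, gr)
        if learn_noise:
            grads["log_q"] += gq * Qd
            grads["log_r"] += gr * Rd
    else:
        _k.backward_window(
            kf_cache["regime"], kf_cache["x_prev"], kf_cache["phi"],
            kf_cache["x_pred"], kf_cache["e"], kf_cache["K"],
            kf_cache["Sinv"],
            roll_cache["regime"], roll_cache["x_prev"], roll_cache["phi"],
            roll_cache["states"],
            np.ascontiguousarray(y_fut, dtype=float),
            np.ascontiguousarray(Ms, dtype=float),
            np.ascontiguousarray(gam, dtype=float),
            np.ascontiguousarray(W, dtype=float),
            svec, th["d"], th["c"], np.ascontiguousarray(H, dtype=float),
            burn_in, DECAY_SIGN, learn_H, whiten,
            gW, grads["_Gam"], gd, gsvec, gvoff, gc, gH)
    grads["Wee"] += gW[:ne, :ne]
    grads["wie"] += np.diag(gW[:ne, ne:])
    grads["Wei"] += gW[ne:, :ne]
    grads["wii"] += np.diag(gW[ne:, ne:])
    grads["d"] += gd
    grads["s_exc"] += np.sum(gsvec[:ne])
    grads["s_inh"] += np.sum(gsvec[ne:])
    grads["voff"] += gvoff
    grads["c"] += gc
    if learn_H:
        grads["H"] += gH
    if learn_noise and not full_cov:
        gq[:] = 0.0
        gr[:] = 0.0
        _k.noise_grads(kf_cache["e"], kf_cache["Sinv"],
                       np.ascontiguousarray(H, dtype=float),
                       burn_in, gq, gr)
        grads["log_q"] += gq * Qd
        grads["log_r"] += gr * Rd


def _factor_gamma_grads(th, grads) -> None:
    """Convert accumulated dense dL/dGamma into factor gradients."""
    m = th["U"].shape[0]
    for i in range(m):
        Gi = grads["_Gam"][i]
        grads["U"][i] += Gi @ th["Vg"][i]
        grads["Vg"][i] += Gi.T @ th["U"][i]
    del grads["_Gam"]


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def kalman_filter_window(params: ModelParameters, y_window: np.ndarray,
                         labels_window, x0: np.ndarray | None = None,
                         P0: np.ndarray | None = None):
    """Extended Kalman filter over a data window.

    Predicts with the regime-appropriate modulated dynamics, linearizes the
    Jacobian at the current estimate, and updates with the observation
    equation.  Returns (filtered means (n, L), final covariance, summed
    innovation error).
    """
    y = np.asarray(y_window, dtype=float)
    labels = np.asarray(labels_window, dtype=int).ravel()
    if y.ndim != 2 or y.shape[1] != labels.size:
        raise ValueError("y_window must be channels x L matching labels")
    if np.min(labels) < 1 or np.max(labels) > params.m:
        raise IndexError("window label out of range 1..m")
    n = params.n
    x0 = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).ravel()
    P0 = np.eye(n) if P0 is None else np.asarray(P0, dtype=float)
    cfg = FitConfig()
    th = _theta_from_params(params, cfg)
    _, _, Ms, svec = _assemble_theta(th, params.n_exc, params.n_inh)
    Qd = np.diag(params.Q).astype(float)
    Rd = np.diag(params.R).astype(float)
    xs, P, err, _ = _ekf_forward(y, labels, x0, P0, Ms, svec, th["d"],
                                 th["voff"], th["c"], params.H, Qd, Rd)
    return xs, P, err


def free_sim_predict(params: ModelParameters, x_hat: np.ndarray, labels_future,
                     horizon: int | None = None,
                     y_future: np.ndarray | None = None):
    """Noiseless forward rollout from a state estimate.

    Returns (predicted observations (channels, horizon), summed squared
    prediction error vs ``y_future`` or None when no data is supplied).
    """
    labels = np.asarray(labels_future, dtype=int).ravel()
    if horizon is None:
        horizon = labels.size
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    labels = labels[:horizon]
    if labels.size < horizon:
        raise ValueError("labels_future shorter than horizon")
    cfg = FitConfig()
    th = _theta_from_params(params, cfg)
    _, _, Ms, svec = _assemble_theta(th, params.n_exc, params.n_inh)
    y_fut = None if y_future is None else np.asarray(y_future, dtype=float)[:, :horizon]
    _, preds, err, _ = _rollout_forward(
        np.asarray(x_hat, dtype=float).ravel(), labels, Ms, svec,
        th["d"], th["voff"], th["c"], params.H, y_fut)
    return preds, (err if y_fut is not None else None)


def apply_constraints(params: ModelParameters,
                      pin_gamma1: bool = False) -> ModelParameters:
    """Project a parameter bundle onto the structural constraint set.

    Elementwise clamps: Wee/Wei >= 0 (masked entries reset to exact 0),
    Wie/Wii <= 0 and diagonal, modulation factors >= 0 (baseline factors
    reset to exact ones when pinned), and Q/R symmetrized with eigenvalues
    floored at 1e-6.  Idempotent; feasible inputs pass through unchanged.
    """
    p = params.copy()
    np.clip(p.W.Wee, 0.0, None, out=p.W.Wee)
    np.clip(p.W.Wei, 0.0, None, out=p.W.Wei)
    p.W.Wee[~p.W.mask_ee] = 0.0
    p.W.Wei[~p.W.mask_ei] = 0.0
    p.W.Wie = np.diag(np.clip(np.diag(p.W.Wie), None, 0.0))
    p.W.Wii = np.diag(np.clip(np.diag(p.W.Wii), None, 0.0))
    for i, g in enumerate(p.gammas):
        if pin_gamma1 and i == 0:
            g.u = np.ones_like(g.u)
            g.v = np.ones_like(g.v)
            g.pinned = True
        else:
            np.clip(g.u, 0.0, None, out=g.u)
            np.clip(g.v, 0.0, None, out=g.v)
    for attr in ("Q", "R"):
        S = getattr(p, attr)
        S = 0.5 * (S + S.T)
        w, Uv = np.linalg.eigh(S)
        w = np.clip(w, 1e-6, None)
        setattr(p, attr, (Uv * w) @ Uv.T)
    return p


def random_init(n_exc: int, n_inh: int, m: int, H: np.ndarray, Q: np.ndarray,
                R: np.ndarray, mask_ee: np.ndarray | None = None,
                mask_ei: np.ndarray | None = None,
                seed: int | np.random.Generator | None = None,
                pin_gamma1: bool = False) -> ModelParameters:
    """Random initial parameters with given lead field and noise covariances.

    W blocks start as small-magnitude, correctly signed uniforms under the
    sparsity mask (a fresh seeded random 75% mask when none is given);
    modulation factors start near 1; decay/slope/offset/bias start at the
    standard defaults (0.65/0.8 decay, slopes 2.5/1, zero offset and bias).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_exc + n_inh
    if mask_ee is None:
        mask_ee = random_offdiag_mask(n_exc, n_exc, rng)
    if mask_ei is None:
        mask_ei = random_offdiag_mask(n_inh, n_exc, rng)
    Wee = 0.1 * rng.uniform(size=(n_exc, n_exc))
    Wei = 0.1 * rng.uniform(size=(n_inh, n_exc))
    Wee[~np.asarray(mask_ee, dtype=bool)] = 0.0
    Wei[~np.asarray(mask_ei, dtype=bool)] = 0.0
    W = StructuredConnectivity(
        n_exc, n_inh, Wee, np.diag(-0.1 * rng.uniform(size=n_exc)),
        Wei, np.diag(-0.1 * rng.uniform(size=n_inh)), mask_ee, mask_ei)
    gammas = []
    for i in range(1, m + 1):
        if pin_gamma1 and i == 1:
            gammas.append(ModulationMatrix.ones(1, n, pinned=True))
        else:
            u = np.clip(rng.normal(1.0, 0.05, size=n), 0.0, None)
            v = np.clip(rng.normal(1.0, 0.05, size=n), 0.0, None)
            gammas.append(ModulationMatrix(i, u, v))
    D = np.concatenate([np.full(n_exc, 0.65), np.full(n_inh, 0.8)])
    return ModelParameters(W=W, gammas=gammas, D=D, s_exc=2.5, s_inh=1.0,
                           V=np.zeros(n), C=np.zeros(n),
                           H=np.asarray(H, dtype=float),
                           Q=np.asarray(Q, dtype=float),
                           R=np.asarray(R, dtype=float))


class _Nadam:
    """NADAM (Nesterov-accelerated Adam) over a dict of arrays."""

    def __init__(self, keys, cfg: FitConfig):
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.cfg = cfg
        self.t = 0

    def step(self, theta: dict, grads: dict, active_keys,
             lr: float | None = None) -> None:
        self.t += 1
        lr = self.cfg.learning_rate if lr is None else lr
        b1, b2 = self.cfg.beta1, self.cfg.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k in active_keys:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * g
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * g * g
            m_hat = self.m[k] / bc1
            v_hat = self.v[k] / bc2
            update = (b1 * m_hat + (1.0 - b1) * g / bc1) \
                / (np.sqrt(v_hat) + self.cfg.adam_eps)
            theta[k] = theta[k] - lr * update


def _valid_window_starts(T: int, span: int, boundaries) -> np.ndarray:
    """Window start indices whose [start, start+span) avoids session seams."""
    starts = np.arange(0, T - span + 1)
    if boundaries:
        keep = np.ones(starts.size, dtype=bool)
        for b in boundaries:
            if b <= 0 or b >= T:
                continue
            # a window straddles seam b iff start < b < start + span
            lo, hi = max(0, b - span + 1), min(starts.size, b)
            keep[lo:hi] = False
        starts = starts[keep]
    if starts.size == 0:
        raise ValueError("recording too short for the configured window span")
    return starts


def fit(recording: LabeledRecording, config: FitConfig | None = None,
        init: ModelParameters | str = "random") -> FitResult:
    """Fit a modulated network model to a labeled recording.

    ``init`` is either a full ModelParameters bundle (its H/Q/R and
    sparsity masks are taken as the starting point; pass the true values
    for recovery experiments) or the string "random", which builds a
    default lead field ``[I - 0.05 11^T | 0]`` with one channel per
    excitatory population and standard noise initializations Q=0.25I,
    R=1.2I.
    """
    cfg = config or FitConfig()
    m = recording.m
    if m < 1:
        raise ValueError("recording has no regime labels")
    present = np.unique(recording.labels)
    if not np.array_equal(present, np.arange(1, m + 1)):
        raise ValueError(f"labels must cover 1..{m}; found {present}")
    nc = recording.n_channels
    if isinstance(init, str):
        if init != "random":
            raise ValueError("init must be ModelParameters or 'random'")
        Hexc = np.eye(nc) - 0.05 * np.ones((nc, nc))
        H = np.hstack([Hexc, np.zeros((nc, nc))])
        init = random_init(nc, nc, m, H, 0.25 * np.eye(2 * nc),
                           1.2 * np.eye(nc), seed=cfg.seed,
                           pin_gamma1=cfg.pin_gamma1)
    if init.m != m:
        raise ValueError("init has a different number of regimes than labels")
    ne, ni = init.n_exc, init.n_inh
    n = ne + ni
    mask_ee, mask_ei = init.W.mask_ee, init.W.mask_ei

    th = _theta_from_params(init, cfg)
    _project_theta(th, mask_ee, mask_ei, cfg)
    rng = np.random.default_rng(cfg.seed)
    opt = _Nadam(list(th.keys()), cfg)
    active = ["Wee", "Wei", "wie", "wii", "U", "Vg", "d", "s_exc", "s_inh",
              "voff", "c"]
    if cfg.learn_H:
        active.append("H")
    if cfg.learn_noise:
        active += ["log_q", "log_r"]

    span = cfg.kalman_window_len + cfg.free_sim_horizon
    T_train = recording.T
    holdout_tiles = []
    if cfg.holdout_frac > 0.0:
        T_hold = int(round(cfg.holdout_frac * recording.T))
        if T_hold >= span:
            T_train = recording.T - T_hold
            holdout_tiles = [int(s0) for s0 in
                             np.arange(T_train, recording.T - span + 1, span)]
    starts = _valid_window_starts(T_train, span,
                                  [b for b in recording.session_boundaries
                                   if b < T_train])
    y = recording.y
    labels = recording.labels

    losses = np.zeros((cfg.max_iterations, 2))
    window_log = np.zeros(cfg.max_iterations, dtype=int)
    ema = None
    alpha = 1.0 - 0.5 ** (1.0 / cfg.ema_half_life)
    last_check = None
    converged = False
    x0 = np.zeros(n)
    P0 = np.eye(n)
    last_stable = _params_from_theta(th, init, cfg)
    n_bad = 0
    it = 0

    def _holdout_score() -> float:
        Wh, gamh, Msh, svech = _assemble_theta(th, ne, ni)
        Qdh = np.exp(th["log_q"])
        Rdh = np.exp(th["log_r"])
        tot = 0.0
        for s0 in holdout_tiles:
            slk = slice(s0, s0 + cfg.kalman_window_len)
            slf = slice(s0 + cfg.kalman_window_len, s0 + span)
            xsh, _, keh, _ = _ekf_forward(
                y[:, slk], labels[slk], x0, P0, Msh, svech, th["d"],
                th["voff"], th["c"], th["H"], Qdh, Rdh,
                burn_in=cfg.kalman_burn_in)
            _, _, feh, _ = _rollout_forward(
                xsh[:, -1], labels[slf], Msh, svech, th["d"], th["voff"],
                th["c"], th["H"], y[:, slf])
            tot += keh + feh
        return tot

    best_score = np.inf
    best_th = None
    patience_left = cfg.holdout_patience
    tail_start = int(np.floor((1.0 - cfg.tail_average_frac)
                              * cfg.max_iterations))
    avg_keys = [k for k in th if k != "s_exc" and k != "s_inh"]
    tail_sum = None
    tail_count = 0

    for it in range(cfg.max_iterations):
        if cfg.lr_schedule == "cosine":
            frac = it / max(1, cfg.max_iterations - 1)
            lr = cfg.learning_rate * (
                cfg.lr_min_frac
                + (1.0 - cfg.lr_min_frac) * 0.5 * (1.0 + np.cos(np.pi * frac)))
        else:
            lr = cfg.learning_rate
        full_phase = (cfg.full_batch_frac > 0.0
                      and it >= (1.0 - cfg.full_batch_frac) * cfg.max_iterations)
        if full_phase:
            batch_starts = [int(s) for s in
                            np.arange(0, T_train - span + 1, span)
                            if s in starts or not recording.session_boundaries]
        else:
            batch_starts = [int(starts[rng.integers(starts.size)])
                            for _ in range(cfg.batch_windows)]
        start = batch_starts[0]
        try:
            W, gam, Ms, svec = _assemble_theta(th, ne, ni)
            Qd = np.exp(th["log_q"])
            Rd = np.exp(th["log_r"])
            grads = _zero_grads(th)
            kerr = ferr = 0.0
            for j, start in enumerate(batch_starts):
                sl_k = slice(start, start + cfg.kalman_window_len)
                sl_f = slice(start + cfg.kalman_window_len, start + span)
                xs, _, ke, kf_cache = _ekf_forward(
                    y[:, sl_k], labels[sl_k], x0, P0, Ms, svec, th["d"],
                    th["voff"], th["c"], th["H"], Qd, Rd,
                    burn_in=cfg.kalman_burn_in,
                    whiten=cfg.innovation_weighting == "whitened")
                _, _, fe, roll_cache = _rollout_forward(
                    xs[:, -1], labels[sl_f], Ms, svec, th["d"], th["voff"],
                    th["c"], th["H"], y[:, sl_f])
                _backward_window(th, grads, W, gam, Ms, svec, th["H"],
                                 kf_cache, roll_cache, y[:, sl_k], y[:, sl_f],
                                 cfg.kalman_burn_in, cfg.learn_H,
                                 cfg.learn_noise, ne,
                                 whiten=cfg.innovation_weighting == "whitened",
                                 full_cov=cfg.covariance_backprop)
                kerr += ke / len(batch_starts)
                ferr += fe / len(batch_starts)
            _factor_gamma_grads(th, grads)
            if cfg.weight_decay > 0.0:
                scale = cfg.weight_decay * len(batch_starts) \
                    * cfg.kalman_window_len
                for k in ("Wee", "Wei", "wie", "wii"):
                    grads[k] = grads[k] + scale * th[k]
            if cfg.learn_noise and cfg.noise_grad_scale != 1.0:
                grads["log_q"] *= cfg.noise_grad_scale
                grads["log_r"] *= cfg.noise_grad_scale
            finite = all(np.all(np.isfinite(np.asarray(grads[k])))
                         for k in active)
            if not finite:
                raise FitDivergenceError("non-finite gradient")
        except FitDivergenceError:
            n_bad += 1
            losses[it] = losses[it - 1] if it > 0 else np.nan
            window_log[it] = start
            if n_bad > cfg.max_bad_iterations:
                raise FitDivergenceError(
                    "persistent divergence during fitting", last_stable)
            continue
        n_bad = 0
        opt.step(th, grads, active, lr=lr)
        _project_theta(th, mask_ee, mask_ei, cfg)
        losses[it] = (kerr, ferr)
        window_log[it] = start
        if it >= tail_start:
            if tail_sum is None:
                tail_sum = {k: np.array(th[k], dtype=float, copy=True)
                            for k in avg_keys}
            else:
                for k in avg_keys:
                    tail_sum[k] += th[k]
            tail_count += 1
        combined = kerr + ferr
        ema = combined if ema is None else (1 - alpha) * ema + alpha * combined
        if (it + 1) % cfg.n_windows_per_epoch == 0:
            last_stable = _params_from_theta(th, init, cfg)
            if holdout_tiles:
                score = _holdout_score()
                if score < best_score * (1.0 - 1e-4):
                    best_score = score
                    best_th = {k: np.array(v, dtype=float, copy=True)
                               for k, v in th.items()}
                    patience_left = cfg.holdout_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        converged = True
                        break
            if last_check is not None and last_check > 0:
                if abs(ema - last_check) / last_check < cfg.convergence_tol:
                    converged = True
                    break
            last_check = ema

    n_done = it + 1
    if best_th is not None:
        th = best_th
        _project_theta(th, mask_ee, mask_ei, cfg)
        tail_count = 0
    if tail_count > 1:
        # tail averaging: iterate-averaged parameters suppress the random
        # walk that stochastic window draws induce in weakly determined
        # directions; the averaged point stays feasible (the constraint set
        # is convex in each factor) and is re-projected below anyway.
        for k in avg_keys:
            th[k] = tail_sum[k] / tail_count
        _project_theta(th, mask_ee, mask_ei, cfg)
    params = apply_constraints(_params_from_theta(th, init, cfg),
                               pin_gamma1=cfg.pin_gamma1)
    params.validate()
    return FitResult(params=params, loss_trace=losses[:n_done],
                     window_log=window_log[:n_done], converged=converged,
                     n_iterations=n_done)
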