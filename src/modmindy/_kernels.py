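"""Numba-compiled inner loops of the dual-estimation engine.

The sequential filter/rollout recursions and their reverse-mode
accumulation are Python-loop bound at the small matrix sizes this model
uses (n of order 20), so the hot paths are compiled.  All kernels are
pure functions of arrays; the Python-level API in ``fit`` wraps them.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NOPYTHON = dict(cache=True)


@njit(**_NOPYTHON)
def ekf_forward(y, labels, x0, P0, Ms, svec, d, voff, c, H, Qd, Rd,
                burn_in, decay_sign, Kfix, use_fixed, whiten):
    """EKF forward pass with caches for the backward pass.

    Returns (xs, P, err, x_prev, phi_c, x_pred_c, e_c, K_c, Sinv_c, bad_t);
    bad_t >= 0 flags divergence at that step.  ``use_fixed`` replays the
    supplied gain sequence (finite-difference validation of the backward
    pass, which treats the gains as constants).
    """
    nc, L = y.shape
    n = x0.size
    x = x0.copy()
    P = P0.copy()
    xs = np.empty((n, L))
    x_prev = np.empty((n, L))
    phi_c = np.empty((n, L))
    x_pred_c = np.empty((n, L))
    e_c = np.empty((nc, L))
    K_c = np.empty((L, n, nc))
    Sinv_c = np.empty((L, nc, nc))
    Pf_c = np.empty((L, n, n))
    Pp_c = np.empty((L, n, n))
    err = 0.0
    for t in range(L):
        i = labels[t] - 1
        M = Ms[i]
        z = svec * x + voff
        phi = np.tanh(z)
        x_pred = x + M @ phi + decay_sign * d * x + c
        for a in range(n):
            if not np.isfinite(x_pred[a]):
                return (xs, P, err, x_prev, phi_c, x_pred_c, e_c, K_c,
                        Sinv_c, Pf_c, Pp_c, t)
        dphi = (1.0 - phi * phi) * svec
        F = M * dphi.reshape(1, n)
        for a in range(n):
            F[a, a] += 1.0 + decay_sign * d[a]
        P_pred = F @ P @ F.T
        for a in range(n):
            P_pred[a, a] += Qd[a]
        e = y[:, t] - H @ x_pred
        if use_fixed:
            K = Kfix[t].copy()
            Sinv = np.eye(nc)
        else:
            S = H @ P_pred @ H.T
            for a in range(nc):
                S[a, a] += Rd[a]
            S = 0.5 * (S + S.T)
            Sinv = np.linalg.inv(S)
            bad = False
            for a in range(nc):
                for b2 in range(nc):
                    if not np.isfinite(Sinv[a, b2]):
                        bad = True
            if bad:
                for a in range(nc):
                    S[a, a] += 1e-8
                Sinv = np.linalg.inv(S)
            K = P_pred @ H.T @ Sinv
        x_prev[:, t] = x
        phi_c[:, t] = phi
        x_pred_c[:, t] = x_pred
        e_c[:, t] = e
        K_c[t] = K
        Sinv_c[t] = Sinv
        Pp_c[t] = P_pred
        x = x_pred + K @ e
        KH = K @ H
        P = P_pred - KH @ P_pred
        P = 0.5 * (P + P.T)
        Pf_c[t] = P
        xs[:, t] = x
        if t >= burn_in:
            if whiten:
                err += e @ (Sinv @ e)
            else:
                err += e @ e
    return xs, P, err, x_prev, phi_c, x_pred_c, e_c, K_c, Sinv_c, Pf_c, Pp_c, -1


@njit(**_NOPYTHON)
def rollout_forward(x_start, labels, Ms, svec, d, voff, c, H, y_fut,
                    decay_sign):
    """Noiseless rollout with caches; returns (states, err, x_prev, phi_c,
    bad_k)."""
    h = labels.size
    n = x_start.size
    x = x_start.copy()
    states = np.empty((n, h))
    x_prev = np.empty((n, h))
    phi_c = np.empty((n, h))
    err = 0.0
    for k in range(h):
        M = Ms[labels[k] - 1]
        phi = np.tanh(svec * x + voff)
        x_prev[:, k] = x
        phi_c[:, k] = phi
        x = x + M @ phi + decay_sign * d * x + c
        for a in range(n):
            if not np.isfinite(x[a]):
                return states, err, x_prev, phi_c, k
        states[:, k] = x
        r = y_fut[:, k] - H @ x
        err += r @ r
    return states, err, x_prev, phi_c, -1


@njit(**_NOPYTHON)
def backward_window(labels_k, x_prev_k, phi_k, x_pred_k, e_k, K_k, Sinv_k,
                    labels_f, x_prev_f, phi_f, states_f,
                    y_fut, Ms, gam, W, svec, d, c, H,
                    burn_in, decay_sign, learn_H, whiten,
                    gW, gGam, gd, gsvec, gvoff, gc, gH):
    """Reverse-mode accumulation through the free simulation (exact BPTT)
    and the Kalman mean recursion (gains frozen).  Gradients are added
    into the provided output arrays.  Returns nothing."""
    n = d.size
    h = labels_f.size
    L = labels_k.size
    lam = np.zeros(n)
    # free simulation
    for k in range(h - 1, -1, -1):
        i = labels_f[k] - 1
        x_prev = x_prev_f[:, k]
        phi = phi_f[:, k]
        x_post = states_f[:, k]
        r = y_fut[:, k] - H @ x_post
        lam = lam - 2.0 * (H.T @ r)
        if learn_H:
            for a in range(gH.shape[0]):
                for b2 in range(n):
                    gH[a, b2] += -2.0 * r[a] * x_post[b2]
        # step backward
        M = Ms[i]
        for a in range(n):
            for b2 in range(n):
                gv = lam[a] * phi[b2]
                gW[a, b2] += gv * gam[i, a, b2]
                gGam[i, a, b2] += gv * W[a, b2]
        a_vec = M.T @ lam
        dz = a_vec * (1.0 - phi * phi)
        for a in range(n):
            gsvec[a] += dz[a] * x_prev[a]
            gvoff[a] += dz[a]
            gc[a] += lam[a]
            gd[a] += decay_sign * lam[a] * x_prev[a]
        lam = lam + decay_sign * d * lam + svec * dz
    # Kalman phase
    for t in range(L - 1, -1, -1):
        K = K_k[t]
        e = e_k[:, t]
        g_pred = lam - H.T @ (K.T @ lam)
        if learn_H:
            KTlam = K.T @ lam
            for a in range(KTlam.size):
                for b2 in range(n):
                    gH[a, b2] += -KTlam[a] * x_pred_k[b2, t]
        if t >= burn_in:
            if whiten:
                ew = Sinv_k[t] @ e
            else:
                ew = e.copy()
            g_pred = g_pred - 2.0 * (H.T @ ew)
            if learn_H:
                for a in range(e.size):
                    for b2 in range(n):
                        gH[a, b2] += -2.0 * ew[a] * x_pred_k[b2, t]
        i = labels_k[t] - 1
        M = Ms[i]
        phi = phi_k[:, t]
        x_prev = x_prev_k[:, t]
        for a in range(n):
            for b2 in range(n):
                gv = g_pred[a] * phi[b2]
                gW[a, b2] += gv * gam[i, a, b2]
                gGam[i, a, b2] += gv * W[a, b2]
        a_vec = M.T @ g_pred
        dz = a_vec * (1.0 - phi * phi)
        for a in range(n):
            gsvec[a] += dz[a] * x_prev[a]
            gvoff[a] += dz[a]
            gc[a] += g_pred[a]
            gd[a] += decay_sign * g_pred[a] * x_prev[a]
        lam = g_pred + decay_sign * d * g_pred + svec * dz


@njit(**_NOPYTHON)
def noise_grads(e_k, Sinv_k, H, burn_in, gq, gr):
    """One-step innovation NLL gradients w.r.t. the Q/R diagonals."""
    nc, L = e_k.shape
    n = H.shape[1]
    for t in range(burn_in, L):
        Sinv = Sinv_k[t]
        se = Sinv @ e_k[:, t]
        for a in range(nc):
            gr[a] += Sinv[a, a] - se[a] * se[a]
        # gq_b = [H^T (Sinv - se se^T) H]_bb
        SH = Sinv @ H  # (nc, n)
        seH = se @ H   # (n,)
        for b2 in range(n):
            acc = 0.0
            for a in range(nc):
                acc += H[a, b2] * SH[a, b2]
            gq[b2] += acc - seH[b2] * seH[b2]


@njit(**_NOPYTHON)
def backward_window_full(labels_k, x_prev_k, phi_k, x_pred_k, e_k, K_k,
                         Sinv_k, Pf_k, Pp_k, x0, P0,
                         labels_f, x_prev_f, phi_f, states_f,
                         y_fut, Ms, gam, W, svec, d, c, H, Qd, Rd,
                         burn_in, decay_sign, learn_H,
                         gW, gGam, gd, gsvec, gvoff, gc, gH, gq, gr):
    """Reverse-mode accumulation with the full covariance recursion
    included: the Kalman gain's dependence on the parameters (through the
    linearized Jacobian, the predicted covariance, and the innovation
    covariance) is differentiated, so parameters that shape how latent
    states are *estimated* — not just how they evolve — receive gradient.
    ``gq``/``gr`` receive the Q/R diagonal gradients arising through the
    gain path."""
    n = d.size
    nc = H.shape[0]
    h = labels_f.size
    L = labels_k.size
    lam = np.zeros(n)
    # free simulation (exact BPTT, no covariances involved)
    for k in range(h - 1, -1, -1):
        i = labels_f[k] - 1
        x_prev = x_prev_f[:, k]
        phi = phi_f[:, k]
        x_post = states_f[:, k]
        r = y_fut[:, k] - H @ x_post
        lam = lam - 2.0 * (H.T @ r)
        if learn_H:
            for a in range(nc):
                for b2 in range(n):
                    gH[a, b2] += -2.0 * r[a] * x_post[b2]
        M = Ms[i]
        for a in range(n):
            for b2 in range(n):
                gv = lam[a] * phi[b2]
                gW[a, b2] += gv * gam[i, a, b2]
                gGam[i, a, b2] += gv * W[a, b2]
        a_vec = M.T @ lam
        dz = a_vec * (1.0 - phi * phi)
        for a in range(n):
            gsvec[a] += dz[a] * x_prev[a]
            gvoff[a] += dz[a]
            gc[a] += lam[a]
            gd[a] += decay_sign * lam[a] * x_prev[a]
        lam = lam + decay_sign * d * lam + svec * dz
    # Kalman phase with covariance adjoints
    lamP = np.zeros((n, n))
    I_n = np.eye(n)
    for t in range(L - 1, -1, -1):
        i = labels_k[t] - 1
        M = Ms[i]
        phi = phi_k[:, t]
        x_prev = x_prev_k[:, t]
        e = e_k[:, t]
        K = K_k[t]
        Sinv = Sinv_k[t]
        P_pred = Pp_k[t]
        # P_filt symmetrization adjoint
        lamPf = 0.5 * (lamP + lamP.T)
        # x_filt = x_pred + K e
        GK = np.outer(lam, e)
        lam_pred = lam - H.T @ (K.T @ lam)
        if learn_H:
            KTlam = K.T @ lam
            for a in range(nc):
                for b2 in range(n):
                    gH[a, b2] += -KTlam[a] * x_pred_k[b2, t]
        if t >= burn_in:
            lam_pred = lam_pred - 2.0 * (H.T @ e)
            if learn_H:
                for a in range(nc):
                    for b2 in range(n):
                        gH[a, b2] += -2.0 * e[a] * x_pred_k[b2, t]
        # P_filt = (I - K H) P_pred
        IKH = I_n - K @ H
        GK += -lamPf @ P_pred @ H.T
        lamPp = IKH.T @ lamPf
        if learn_H:
            GH_P = -(K.T @ lamPf @ P_pred)
            for a in range(nc):
                for b2 in range(n):
                    gH[a, b2] += GH_P[a, b2]
        # K = P_pred H^T Sinv
        lamPp += GK @ (Sinv @ H)
        GS = -(K.T @ GK @ Sinv)
        GS = 0.5 * (GS + GS.T)
        # S = H P_pred H^T + diag(Rd)
        lamPp += H.T @ GS @ H
        for a in range(nc):
            gr[a] += GS[a, a]
        if learn_H:
            # S and K stages: H enters S = H P_pred H^T and K = P_pred H^T Sinv
            HP = H @ P_pred
            GH_S = 2.0 * (GS @ HP)
            SK = Sinv.T @ GK.T @ P_pred
            for a in range(nc):
                for b2 in range(n):
                    gH[a, b2] += GH_S[a, b2] + SK[a, b2]
        # P_pred = F P F^T + diag(Qd)
        lamPp_sym = lamPp
        for a in range(n):
            gq[a] += lamPp_sym[a, a]
        dphi = (1.0 - phi * phi) * svec
        F = M * dphi.reshape(1, n)
        for a in range(n):
            F[a, a] += 1.0 + decay_sign * d[a]
        if t == 0:
            P_prev = P0
        else:
            P_prev = Pf_k[t - 1]
        FP = F @ P_prev
        GF = (lamPp_sym + lamPp_sym.T) @ FP
        lamP = F.T @ lamPp_sym @ F
        # F = I - diag(d) + M diag(dphi)
        gdphi = np.zeros(n)
        for b2 in range(n):
            acc = 0.0
            for a in range(n):
                acc += GF[a, b2] * M[a, b2]
            gdphi[b2] = acc
        for a in range(n):
            for b2 in range(n):
                gm = GF[a, b2] * dphi[b2]
                gW[a, b2] += gm * gam[i, a, b2]
                gGam[i, a, b2] += gm * W[a, b2]
            gd[a] += decay_sign * GF[a, a]
        # dphi_j = s_j (1 - phi_j^2); z_j = s_j x_j + v_j
        one_m = 1.0 - phi * phi
        g_z = gdphi * (-2.0) * svec * phi * one_m
        for a in range(n):
            gsvec[a] += gdphi[a] * one_m[a] + g_z[a] * x_prev[a]
            gvoff[a] += g_z[a]
        # dynamics mean: x_pred = x_prev + M phi + decay_sign d x_prev + c
        for a in range(n):
            for b2 in range(n):
                gv = lam_pred[a] * phi[b2]
                gW[a, b2] += gv * gam[i, a, b2]
                gGam[i, a, b2] += gv * W[a, b2]
        a_vec = M.T @ lam_pred
        dz = a_vec * one_m
        for a in range(n):
            gsvec[a] += dz[a] * x_prev[a]
            gvoff[a] += dz[a]
            gc[a] += lam_pred[a]
            gd[a] += decay_sign * lam_pred[a] * x_prev[a]
        lam = lam_pred + decay_sign * d * lam_pred + svec * dz + g_z * svec
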