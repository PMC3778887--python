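"""Compiled forward pass of the generative model with parameter sensitivities.

Integrates the coupled neural-hemodynamic system with the same Heun-drift
scheme as the simulator and simultaneously propagates the sensitivity matrix
S = dz/d(theta) through the integration, so that one pass yields both the
predicted BOLD time series and its Jacobian with respect to all free
evolution parameters (and, for stochastic inversion, the per-scan neural
innovations).

Evolution parameters are encoded positionally:
    block 0: A[r, c]            -> (pi=r, pj=c, pk=0)
    block 1: B^(i)[r, c]        -> (pi=i, pj=r, pk=c)
    block 2: C[r, c]            -> (pi=r, pj=c, pk=0)
    block 3: D^(j)[r, c]        -> (pi=j, pj=r, pk=c)
    block 4: basis coeff [r, k] -> (pi=r, pj=k, pk=0)
The neural flow is linear in every one of these, which keeps the parameter
part of the sensitivity update sparse.  Hemodynamic parameters, when free,
are handled by finite differences at the python level (see inference).
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATE_CAP = 1e6


@njit(cache=True)
def _neural_drift(x, u_t, basis_t, delta_t, A, Bst, C, Dst, Cb):
    n = x.shape[0]
    dx = A @ x + C @ u_t
    for i in range(Bst.shape[0]):
        if u_t[i] != 0.0:
            dx += u_t[i] * (Bst[i] @ x)
    for j in range(Dst.shape[0]):
        if x[j] != 0.0:
            dx += x[j] * (Dst[j] @ x)
    if Cb.shape[1] > 0:
        dx += Cb @ basis_t
    dx += delta_t
    return dx


@njit(cache=True)
def _hemo_drift(H, x, hp):
    """H is (n, 4) hemodynamic states; returns (n, 4) derivatives."""
    n = H.shape[0]
    ks, kf, tau0, alpha, E0 = hp[0], hp[1], hp[2], hp[3], hp[4]
    dH = np.empty((n, 4))
    for r in range(n):
        s, lf, lv, lq = H[r, 0], H[r, 1], H[r, 2], H[r, 3]
        ef = np.exp(lf)
        dH[r, 0] = x[r] - ks * s - kf * (ef - 1.0)
        dH[r, 1] = s * np.exp(-lf)
        dH[r, 2] = (ef - np.exp(lv / alpha)) * np.exp(-lv) / tau0
        E = 1.0 - (1.0 - E0) ** np.exp(-lf)
        dH[r, 3] = (np.exp(lf - lq) * E / E0 - np.exp((1.0 - alpha) * lv / alpha)) / tau0
    return dH


@njit(cache=True)
def _jacobian_z(z, u_t, A, Bst, Dst, hp, out):
    """Full-state Jacobian (5n x 5n) at state z; writes into ``out``."""
    n = A.shape[0]
    out[:, :] = 0.0
    x = z[:n]
    # neural block
    for r in range(n):
        for c in range(n):
            out[r, c] = A[r, c]
    for i in range(Bst.shape[0]):
        if u_t[i] != 0.0:
            for r in range(n):
                for c in range(n):
                    out[r, c] += u_t[i] * Bst[i, r, c]
    for j in range(Dst.shape[0]):
        xj = x[j]
        if xj != 0.0:
            for r in range(n):
                for c in range(n):
                    out[r, c] += xj * Dst[j, r, c]
        # column j picks up D^(j) x
        for r in range(n):
            acc = 0.0
            for c in range(n):
                acc += Dst[j, r, c] * x[c]
            out[r, j] += acc
    # hemodynamic blocks
    ks, kf, tau0, alpha, E0 = hp[0], hp[1], hp[2], hp[3], hp[4]
    for r in range(n):
        o = n + 4 * r
        s, lf, lv, lq = z[o], z[o + 1], z[o + 2], z[o + 3]
        ef = np.exp(lf)
        out[o, r] = 1.0               # ds/dx_n
        out[o, o] = -ks
        out[o, o + 1] = -kf * ef
        out[o + 1, o] = np.exp(-lf)
        out[o + 1, o + 1] = -s * np.exp(-lf)
        out[o + 2, o + 1] = ef * np.exp(-lv) / tau0
        out[o + 2, o + 2] = (-(1.0 / alpha) * np.exp(lv / alpha) * np.exp(-lv)
                             - (ef - np.exp(lv / alpha)) * np.exp(-lv)) / tau0
        om = 1.0 - E0
        E = 1.0 - om ** np.exp(-lf)
        dE = om ** np.exp(-lf) * np.log(om) * np.exp(-lf)
        out[o + 3, o + 1] = (np.exp(lf - lq) * (E + dE) / E0) / tau0
        out[o + 3, o + 2] = -((1.0 - alpha) / alpha) * np.exp((1.0 - alpha) * lv / alpha) / tau0
        out[o + 3, o + 3] = -np.exp(lf - lq) * E / E0 / tau0


@njit(cache=True)
def _add_param_columns(Sdot, x, u_t, basis_t, pb, pi, pj, pk):
    """Add the (sparse) d(flow)/d(theta) contribution to the S derivative."""
    for p in range(pb.shape[0]):
        b = pb[p]
        if b == 0:       # A[r, c]: row pi, value x[pj]
            Sdot[pi[p], p] += x[pj[p]]
        elif b == 1:     # B^(i)[r, c]
            Sdot[pj[p], p] += u_t[pi[p]] * x[pk[p]]
        elif b == 2:     # C[r, c]
            Sdot[pi[p], p] += u_t[pj[p]]
        elif b == 3:     # D^(j)[r, c]
            Sdot[pj[p], p] += x[pi[p]] * x[pk[p]]
        elif b == 4:     # basis [r, k]
            Sdot[pi[p], p] += basis_t[pj[p]]


@njit(cache=True)
def _bold_and_grad(z, n, hp, y_out, gv_out, gq_out):
    V0, nu0, TE, r0, eps0 = hp[5], hp[6], hp[7], hp[8], hp[9]
    k1 = 4.3 * nu0 * hp[4] * TE
    k2 = eps0 * r0 * hp[4] * TE
    k3 = 1.0 - eps0
    for r in range(n):
        lv = z[n + 4 * r + 2]
        lq = z[n + 4 * r + 3]
        ev = np.exp(lv)
        eq = np.exp(lq)
        eqv = np.exp(lq - lv)
        y_out[r] = V0 * (k1 * (1.0 - eq) + k2 * (1.0 - eqv) + k3 * (1.0 - ev))
        gv_out[r] = V0 * (k2 * eqv - k3 * ev)
        gq_out[r] = V0 * (-k1 * eq - k2 * eqv)


@njit(cache=True)
def forward_sens(n, dt, sub, nscan,
                 A, Bst, C, Dst, Cb,
                 u, ub, delta, hp, w,
                 pb, pi, pj, pk,
                 with_w, want_sens, want_state_sens):
    """Heun-drift forward pass with optional sensitivity propagation.

    Returns (status, y, G, xn_scan, xh_scan, Sxn) where status < 0 on
    success and otherwise is the index of the scan interval in which the
    state exceeded the divergence cap.  G has one row per observation in
    scan-major order (row = scan * n + region).  Sxn holds the neural-state
    sensitivity rows at scan times when requested.
    """
    P_evo = pb.shape[0]
    n_w = n * nscan if with_w else 0
    P = P_evo + n_w
    nz = 5 * n
    z = np.zeros(nz)
    S = np.zeros((nz, P if want_sens else 1))
    y = np.zeros((n, nscan))
    G = np.zeros((n * nscan, P if want_sens else 1))
    xn_scan = np.zeros((n, nscan))
    xh_scan = np.zeros((4 * n, nscan))
    Sxn = np.zeros((nscan, n, P) if want_state_sens else (1, 1, 1))
    J0 = np.zeros((nz, nz))
    J1 = np.zeros((nz, nz))
    f0 = np.zeros(nz)
    f1 = np.zeros(nz)
    yb = np.zeros(n)
    gv = np.zeros(n)
    gq = np.zeros(n)
    status = -1
    for k in range(nscan):
        if with_w:
            for r in range(n):
                z[r] += w[r, k]
                if want_sens:
                    S[r, P_evo + k * n + r] += 1.0
        for s_i in range(sub):
            t = k * sub + s_i
            u_t = u[:, t]
            basis_t = ub[:, t]
            delta_t = delta[:, t]
            x = z[:n]
            H = z[n:].reshape(n, 4)
            dxn = _neural_drift(x, u_t, basis_t, delta_t, A, Bst, C, Dst, Cb)
            dH = _hemo_drift(H, x, hp)
            f0[:n] = dxn
            f0[n:] = dH.ravel()
            if want_sens:
                _jacobian_z(z, u_t, A, Bst, Dst, hp, J0)
                Sd0 = J0 @ S
                _add_param_columns(Sd0, x, u_t, basis_t, pb, pi, pj, pk)
            z1 = z + dt * f0
            x1 = z1[:n]
            H1 = z1[n:].reshape(n, 4)
            dxn1 = _neural_drift(x1, u_t, basis_t, delta_t, A, Bst, C, Dst, Cb)
            dH1 = _hemo_drift(H1, x1, hp)
            f1[:n] = dxn1
            f1[n:] = dH1.ravel()
            if want_sens:
                _jacobian_z(z1, u_t, A, Bst, Dst, hp, J1)
                S1 = S + dt * Sd0
                Sd1 = J1 @ S1
                _add_param_columns(Sd1, x1, u_t, basis_t, pb, pi, pj, pk)
                S = S + 0.5 * dt * (Sd0 + Sd1)
            z = z + 0.5 * dt * (f0 + f1)
            cap = 0.0
            for q in range(nz):
                a = abs(z[q])
                if a > cap:
                    cap = a
            if cap > STATE_CAP or not np.isfinite(cap):
                return k, y, G, xn_scan, xh_scan, Sxn
        _bold_and_grad(z, n, hp, yb, gv, gq)
        for r in range(n):
            y[r, k] = yb[r]
            xn_scan[r, k] = z[r]
            for q in range(4):
                xh_scan[4 * r + q, k] = z[n + 4 * r + q]
            if want_sens:
                row = k * n + r
                for p in range(S.shape[1]):
                    G[row, p] = gv[r] * S[n + 4 * r + 2, p] + gq[r] * S[n + 4 * r + 3, p]
        if want_state_sens:
            for r in range(n):
                for p in range(S.shape[1]):
                    Sxn[k, r, p] = S[r, p]
    return status, y, G, xn_scan, xh_scan, Sxn
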