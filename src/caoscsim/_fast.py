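"""Compiled integration backend.

A Dormand–Prince 5(4) adaptive step integrator specialised to the
four-variable model, JIT-compiled with numba.  It exists because ensemble
work (global sensitivity, drug-constant fitting, synthetic-cohort
generation) needs thousands of limit-cycle simulations; a single compiled
trajectory costs a few milliseconds versus a few hundred for the generic
SciPy path, and the two backends agree on the oscillation period to better
than 0.1% (asserted in the test suite).

The parameter vector layout is ``ModelParameters._FIELDS``; index constants
below must stay in sync with it.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# indices into ModelParameters.to_vector()
_DELTA, _KTAU, _KC, _KF, _VS, _GAMMA, _VPM, _A0, _KP, _TMAX, _BP, _KH, \
    _KBAR, _KE, _KPM, _A1, _PS, _KBETA, _KS = range(19)


@njit(cache=True)
def _rhs(y, pv, D1, D2, out):
    c = y[0] if y[0] > 0.0 else 0.0
    ce = y[1] if y[1] > 0.0 else 0.0
    h = y[2]
    if h < 0.0:
        h = 0.0
    elif h > 1.0:
        h = 1.0
    p = y[3] if y[3] > 0.0 else 0.0

    c2 = c * c
    c4 = c2 * c2
    kc4 = pv[_KC] ** 4
    kh4 = pv[_KH] ** 4
    ktau4 = pv[_KTAU] ** 4
    ke4 = pv[_KE] ** 4

    m = c4 / (kc4 + c4)
    hinf = kh4 / (kh4 + c4)
    b_p = p * p / (pv[_KP] * pv[_KP] + p * p)
    alpha = (1.0 - b_p) * (1.0 - m * hinf)
    beta = b_p * m * h
    den = beta + pv[_KBETA] * (beta + alpha)
    po = beta / den if den > 0.0 else 0.0

    j_ipr = pv[_KF] * po * (ce - c)
    j_serca = pv[_VS] * (c2 - pv[_KBAR] * ce * ce) / (c2 + pv[_KS] * pv[_KS])
    j_in = pv[_A0] + D2 * pv[_A1] * ke4 / (ke4 + ce ** 4)
    j_pm = pv[_VPM] * c2 / (pv[_KPM] * pv[_KPM] + c2)
    tau = pv[_TMAX] * ktau4 / (ktau4 + c4)

    out[0] = j_ipr - j_serca + pv[_DELTA] * (j_in - j_pm)
    out[1] = pv[_GAMMA] * (j_serca - j_ipr)
    out[2] = (hinf - h) / tau
    out[3] = D1 * pv[_BP] * pv[_PS] - pv[_BP] * p


@njit(cache=True)
def integrate_rk45(pv, D1, D2, y0, t_end, dt_out, rtol, atol):
    """Adaptive Dormand-Prince 5(4) with linear dense output on a uniform grid.

    Returns (t_grid, states) with states shaped (n_out, 4).  On a non-finite
    state the trajectory is truncated (caller detects the short output).
    """
    n_out = int(t_end / dt_out) + 1
    ts = np.empty(n_out)
    ys = np.empty((n_out, 4))
    y = y0.copy()
    ts[0] = 0.0
    ys[0] = y

    k1 = np.empty(4); k2 = np.empty(4); k3 = np.empty(4); k4 = np.empty(4)
    k5 = np.empty(4); k6 = np.empty(4); k7 = np.empty(4)
    ytmp = np.empty(4); y5 = np.empty(4)
    yprev = y.copy()

    t = 0.0
    tprev = 0.0
    hstep = 0.01
    iout = 1
    t_next = dt_out
    _rhs(y, pv, D1, D2, k1)

    while t < t_end:
        if hstep > t_end - t:
            hstep = t_end - t

        for i in range(4):
            ytmp[i] = y[i] + hstep * 0.2 * k1[i]
        _rhs(ytmp, pv, D1, D2, k2)
        for i in range(4):
            ytmp[i] = y[i] + hstep * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
        _rhs(ytmp, pv, D1, D2, k3)
        for i in range(4):
            ytmp[i] = y[i] + hstep * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i]
                                      + 32.0 / 9.0 * k3[i])
        _rhs(ytmp, pv, D1, D2, k4)
        for i in range(4):
            ytmp[i] = y[i] + hstep * (19372.0 / 6561.0 * k1[i] - 25360.0 / 2187.0 * k2[i]
                                      + 64448.0 / 6561.0 * k3[i] - 212.0 / 729.0 * k4[i])
        _rhs(ytmp, pv, D1, D2, k5)
        for i in range(4):
            ytmp[i] = y[i] + hstep * (9017.0 / 3168.0 * k1[i] - 355.0 / 33.0 * k2[i]
                                      + 46732.0 / 5247.0 * k3[i] + 49.0 / 176.0 * k4[i]
                                      - 5103.0 / 18656.0 * k5[i])
        _rhs(ytmp, pv, D1, D2, k6)
        for i in range(4):
            y5[i] = y[i] + hstep * (35.0 / 384.0 * k1[i] + 500.0 / 1113.0 * k3[i]
                                    + 125.0 / 192.0 * k4[i] - 2187.0 / 6784.0 * k5[i]
                                    + 11.0 / 84.0 * k6[i])
        _rhs(y5, pv, D1, D2, k7)

        err = 0.0
        for i in range(4):
            y4i = y[i] + hstep * (5179.0 / 57600.0 * k1[i] + 7571.0 / 16695.0 * k3[i]
                                  + 393.0 / 640.0 * k4[i] - 92097.0 / 339200.0 * k5[i]
                                  + 187.0 / 2100.0 * k6[i] + 1.0 / 40.0 * k7[i])
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            e = (y5[i] - y4i) / sc
            err += e * e
        err = np.sqrt(err / 4.0)

        if err <= 1.0 or hstep <= 1e-10:
            tprev = t
            for i in range(4):
                yprev[i] = y[i]
            t = t + hstep
            for i in range(4):
                y[i] = y5[i]
                k1[i] = k7[i]  # first-same-as-last
            if not (np.isfinite(y[0]) and np.isfinite(y[1])
                    and np.isfinite(y[2]) and np.isfinite(y[3])):
                return ts[:iout], ys[:iout]
            while t_next <= t and iout < n_out:
                w = (t_next - tprev) / (t - tprev)
                ts[iout] = t_next
                for i in range(4):
                    ys[iout, i] = yprev[i] * (1.0 - w) + y[i] * w
                iout += 1
                t_next += dt_out

        fac = 0.9 * err ** -0.2 if err > 1e-14 else 5.0
        if fac > 5.0:
            fac = 5.0
        elif fac < 0.2:
            fac = 0.2
        hstep *= fac
        if hstep < 1e-10:
            hstep = 1e-10

    return ts[:iout], ys[:iout]
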