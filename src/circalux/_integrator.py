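"""Compiled fixed-step RK4 core for the coupled circadian + sleep system.

The integrator advances the continuous state ``y = (x, x_c, n, H)`` with
classical fourth-order Runge-Kutta on a pre-built time grid that contains
every schedule breakpoint, so light discontinuities always fall on step
boundaries.  The discrete sleep/wake mode is handled by event detection:
threshold crossings of the homeostat are localized by bisection
(re-integrating the partial step) to ~1e-6 h, while light-gate events
(sleep prevention / forced wake at the lux threshold) are resolved at
grid points, where all step changes of the schedules in this study occur.

Parameter packing (plain float64 arrays, for the compiled kernel):

``cp`` = (p, kappa, tau_c, alpha_0, beta, i_0, big_g, mu_vdp, k_light,
period_corr); ``sp`` = (mu, delta, chi, h_wake_asymptote, tau_rise, c_a,
wake_lux_threshold).  A ``wake_lux_threshold`` of ``inf`` disables the
light gate.

Event kinds: 0 = sleep onset, 1 = spontaneous wake (lower-threshold
crossing), 2 = forced wake (light above threshold).
"""

import numpy as np
from numba import njit

PI_12 = np.pi / 12.0

EVENT_ONSET = 0
EVENT_WAKE = 1
EVENT_FORCED_WAKE = 2

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_N_OUT_OF_RANGE = 2


@njit(cache=True)
def _lux_at(t, s0, s1, l0, l1):
    n = s0.shape[0]
    lo = 0
    hi = n
    while lo < hi:
        mid = (lo + hi) // 2
        if s0[mid] <= t:
            lo = mid + 1
        else:
            hi = mid
    i = lo - 1
    if i < 0:
        i = 0
    if i > n - 1:
        i = n - 1
    w = (t - s0[i]) / (s1[i] - s0[i])
    if w < 0.0:
        w = 0.0
    if w > 1.0:
        w = 1.0
    return l0[i] + w * (l1[i] - l0[i])


@njit(cache=True)
def _deriv(t, y, asleep, cp, sp, s0, s1, l0, l1, out):
    x = y[0]
    xc = y[1]
    n = y[2]
    H = y[3]
    I = 0.0
    if not asleep:
        I = _lux_at(t, s0, s1, l0, l1)
    alpha = 0.0
    if I > 0.0:
        alpha = cp[3] * (I / cp[5]) ** cp[0]
    B = cp[6] * alpha * (1.0 - n) * (1.0 - cp[1] * x) * (1.0 - cp[1] * xc)
    omega2 = (24.0 / (cp[9] * cp[2])) ** 2
    out[0] = PI_12 * (xc + B)
    out[1] = PI_12 * (cp[7] * (xc - 4.0 * xc * xc * xc / 3.0) - x * (omega2 + cp[8] * B))
    out[2] = 60.0 * (alpha * (1.0 - n) - cp[4] * n)
    if asleep:
        out[3] = -H / sp[2]
    else:
        out[3] = (sp[3] - H) / sp[4]


@njit(cache=True)
def _rk4(t, h, y, asleep, cp, sp, s0, s1, l0, l1, k1, k2, k3, k4, yt, out):
    _deriv(t, y, asleep, cp, sp, s0, s1, l0, l1, k1)
    for j in range(4):
        yt[j] = y[j] + 0.5 * h * k1[j]
    _deriv(t + 0.5 * h, yt, asleep, cp, sp, s0, s1, l0, l1, k2)
    for j in range(4):
        yt[j] = y[j] + 0.5 * h * k2[j]
    _deriv(t + 0.5 * h, yt, asleep, cp, sp, s0, s1, l0, l1, k3)
    for j in range(4):
        yt[j] = y[j] + h * k3[j]
    _deriv(t + h, yt, asleep, cp, sp, s0, s1, l0, l1, k4)
    for j in range(4):
        out[j] = y[j] + (h / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])


@njit(cache=True)
def integrate(grid, y0, asleep0, cp, sp, s0, s1, l0, l1):
    ng = grid.shape[0]
    X = np.empty((ng, 4))
    A = np.empty(ng, np.int8)
    ev_t = np.empty(4 * ng + 16, np.float64)
    ev_k = np.empty(4 * ng + 16, np.int8)
    nev = 0
    status = STATUS_OK
    fail_t = -1.0

    y = y0.copy()
    ynew = np.empty(4)
    ymid = np.empty(4)
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    yt = np.empty(4)
    asleep = asleep0
    wake_thr = sp[6]

    for i in range(ng):
        t = grid[i]
        # --- gate / threshold check at the grid point (light may have jumped)
        lux_now = _lux_at(t, s0, s1, l0, l1)
        upper = sp[0] + sp[5] * y[0]
        lower = upper - sp[1]
        if asleep:
            if lux_now > wake_thr:
                asleep = False
                ev_t[nev] = t
                ev_k[nev] = EVENT_FORCED_WAKE
                nev += 1
            elif y[3] <= lower:
                asleep = False
                ev_t[nev] = t
                ev_k[nev] = EVENT_WAKE
                nev += 1
        else:
            if y[3] >= upper and lux_now <= wake_thr:
                asleep = True
                ev_t[nev] = t
                ev_k[nev] = EVENT_ONSET
                nev += 1
        X[i, 0] = y[0]
        X[i, 1] = y[1]
        X[i, 2] = y[2]
        X[i, 3] = y[3]
        A[i] = 1 if asleep else 0
        if i == ng - 1:
            break

        # --- advance to the next grid point, flipping mode at crossings
        tb = grid[i + 1]
        for _flip in range(6):
            h = tb - t
            if h <= 1e-12:
                break
            _rk4(t, h, y, asleep, cp, sp, s0, s1, l0, l1, k1, k2, k3, k4, yt, ynew)
            upper_e = sp[0] + sp[5] * ynew[0]
            lower_e = upper_e - sp[1]
            crossed = False
            kind = EVENT_WAKE
            if asleep:
                if ynew[3] <= lower_e:
                    crossed = True
                    kind = EVENT_WAKE
            else:
                # only bisect a genuine within-step H-crossing with the light
                # gate open for the whole step; a gate opening at tb itself is
                # handled by the grid-point check of the next iteration
                lux_a = _lux_at(t, s0, s1, l0, l1)
                lux_e = _lux_at(tb, s0, s1, l0, l1)
                upper_a = sp[0] + sp[5] * y[0]
                if (
                    ynew[3] >= upper_e
                    and y[3] < upper_a
                    and lux_e <= wake_thr
                    and lux_a <= wake_thr
                ):
                    crossed = True
                    kind = EVENT_ONSET
            if not crossed:
                for j in range(4):
                    y[j] = ynew[j]
                t = tb
                break
            # bisection on the partial step width; invariant: condition
            # not met at wlo, met at whi
            wlo = 0.0
            whi = h
            for _ in range(40):
                if whi - wlo < 1e-7:
                    break
                wm = 0.5 * (wlo + whi)
                _rk4(t, wm, y, asleep, cp, sp, s0, s1, l0, l1, k1, k2, k3, k4, yt, ymid)
                um = sp[0] + sp[5] * ymid[0]
                if asleep:
                    met = ymid[3] <= um - sp[1]
                else:
                    met = ymid[3] >= um
                if met:
                    whi = wm
                else:
                    wlo = wm
            _rk4(t, whi, y, asleep, cp, sp, s0, s1, l0, l1, k1, k2, k3, k4, yt, ymid)
            for j in range(4):
                y[j] = ymid[j]
            t = t + whi
            asleep = not asleep
            ev_t[nev] = t
            ev_k[nev] = kind
            nev += 1

        # --- sanity: abort on non-finite or runaway state
        ok = True
        for j in range(4):
            if not np.isfinite(y[j]):
                ok = False
        if abs(y[0]) > 50.0 or abs(y[1]) > 50.0 or abs(y[3]) > 1e6:
            ok = False
        if not ok:
            status = STATUS_NONFINITE
            fail_t = t
            break
        if y[2] < -1e-6 or y[2] > 1.0 + 1e-6:
            status = STATUS_N_OUT_OF_RANGE
            fail_t = t
            break

    n_done = i + 1
    return X[:n_done], A[:n_done], ev_t[:nev].copy(), ev_k[:nev].copy(), status, fail_t
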