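"""Numba kernel for the hybrid BTSLIP integration.

The walker is a delay differential equation (the reflex pathway feeds back
the leg axial force ``delta_p`` seconds in the past), so the kernel uses a
fixed-step classical Runge-Kutta scheme with step ``h <= delta_p`` and a
per-leg ring buffer of (t, Fs) samples: every delayed lookup then falls in
the already-accepted past and is resolved by linear interpolation.  Phase
transitions (touchdown, takeoff), the mid-stance Poincare crossing and fall
guards are located by bisection on the event functions inside the step that
brackets the sign change.

Everything here works on plain float64 scalars/arrays so it compiles under
``@njit``; the public modules (:mod:`btslip.mechanics`, :mod:`btslip.muscle`,
:mod:`btslip.engine`) wrap these functions with dataclass-based interfaces.

State vector layout (10,):
    0 x, 1 y       CoM position, m
    2 vx, 3 vy     CoM velocity, m/s
    4 phi, 5 phid  trunk angle (from horizontal) and rate
    6..9           muscle activations: [RF leg0, HAM leg0, RF leg1, HAM leg1]

Auxiliary output layout (14,):
    0 tau0, 1 tau1             hip torques, N m
    2 g0x, 3 g0y, 4 g1x, 5 g1y per-leg ground reaction forces, N
    6 Fs0, 7 Fs1               leg axial spring forces, N
    8 phih0, 9 phih1           hip angles, rad (NaN for swing legs)
    10 phidoth0, 11 phidoth1   hip angular velocities, rad/s
    12 c0, 13 c1               contact flags
    14 f0, 15 f1               stance-foot x positions (NaN for swing legs)
"""

import numpy as np
from numba import njit

# ---- parameter vector layout -------------------------------------------------
IM, IJ, IRH, IL0, IG, IK, IMU = 0, 1, 2, 3, 4, 5, 6
IFMAX, ILOPT, IVMAX, IW, IC, INECC, IKAP, IRHO, IR0, ILMTU0 = (
    7, 8, 9, 10, 11, 12, 13, 14, 15, 16)
IPREF_RF, IPREF_HAM = 17, 18
ISTIM0, IDELTAP, ITECC, ISTIMLO, ISTIMHI = 19, 20, 21, 22, 23
IGFMCH, IPHIH0 = 24, 25
IH = 26
IFALLY, IFALLPHI = 27, 28
NPAR = 29

NSTATE = 10
NAUX = 16

# controller ids
CTRL_ZERO, CTRL_FMCH, CTRL_NMF, CTRL_PREFLEX = 0, 1, 2, 3

# phases
PH_SINGLE, PH_DOUBLE = 0, 1

# event codes returned by integrate_segment
EV_TOUCHDOWN, EV_TAKEOFF, EV_MIDSTANCE, EV_FALL, EV_TMAX, EV_NAN = 1, 2, 3, 4, 5, 6

# fall reasons
FALL_NONE, FALL_UNLOADED, FALL_LOW_HIP, FALL_PITCH = 0, 1, 2, 3

_BIG = 1e9
_HALFPI = 0.5 * np.pi


# ---- scalar physics ----------------------------------------------------------

@njit(cache=True)
def hip_xy(x, y, phi, r_h):
    """Hip point: r_h below the CoM along the trunk axis."""
    return x - r_h * np.cos(phi), y - r_h * np.sin(phi)


@njit(cache=True)
def spring_force(l, l0, k):
    """Axial leg force, repulsive positive; negative past rest length
    (tension is never transmitted: takeoff fires at GRF_y = 0)."""
    return k * (l0 - l)


@njit(cache=True)
def grf_from(Fs, tau, xh, yh, fx):
    """Per-leg ground reaction force from axial force and hip torque."""
    u = xh - fx
    l2 = u * u + yh * yh
    l = np.sqrt(l2)
    gx = Fs * u / l + tau * yh / l2
    gy = Fs * yh / l - tau * u / l2
    return gx, gy


@njit(cache=True)
def hip_angle(phi, xh, yh, fx):
    """Trunk-leg angle, continuous through mid-stance; ~pi when the leg is
    the downward continuation of an upright trunk."""
    return phi + np.pi - np.arctan2(yh, xh - fx)


@njit(cache=True)
def fl_curve(l_ce, l_opt, w, c):
    """Bell-shaped force-length factor, 1 at l_opt, exp(c) at l_opt*(1+-w)."""
    z = (l_ce - l_opt) / (l_opt * w)
    a = np.abs(z)
    return np.exp(c * a * a * a)


@njit(cache=True)
def fv_curve(v_ce, v_max, kappa, n_ecc):
    """Hill force-velocity factor; v in m/s, lengthening positive,
    v_max < 0.  Clamped to 0 for shortening faster than v_max."""
    if v_ce < 0.0:
        if v_ce <= v_max:
            return 0.0
        return (v_max - v_ce) / (v_max + kappa * v_ce)
    return n_ecc + (n_ecc - 1.0) * (v_max + v_ce) / (7.56 * kappa * v_ce - v_max)


@njit(cache=True)
def sat(x, lo, hi):
    if x < lo:
        return lo
    if x > hi:
        return hi
    return x


@njit(cache=True)
def vbla(vx, vy, mu, g):
    """Velocity-based leg adjustment direction (unnormalized)."""
    return (1.0 - mu) * vx, (1.0 - mu) * vy - mu * g


# ---- history ring buffer -----------------------------------------------------

@njit(cache=True)
def hist_write(hist_t, hist_F, hist_n, leg, t, F):
    nb = hist_t.shape[1]
    idx = hist_n[leg] % nb
    hist_t[leg, idx] = t
    hist_F[leg, idx] = F
    hist_n[leg] += 1


@njit(cache=True)
def hist_lookup(hist_t, hist_F, hist_n, leg, tq):
    """Linear interpolation of the recorded force at time tq; earliest
    stored value for queries before the record, 0 for an empty record."""
    n = hist_n[leg]
    if n == 0:
        return 0.0
    nb = hist_t.shape[1]
    idx = (n - 1) % nb
    if tq >= hist_t[leg, idx]:
        return hist_F[leg, idx]
    m = n if n < nb else nb
    for _ in range(m - 1):
        prev = (idx - 1) % nb
        if hist_t[leg, prev] <= tq:
            t0 = hist_t[leg, prev]
            t1 = hist_t[leg, idx]
            if t1 <= t0:
                return hist_F[leg, idx]
            wgt = (tq - t0) / (t1 - t0)
            return hist_F[leg, prev] * (1.0 - wgt) + hist_F[leg, idx] * wgt
        idx = prev
    return hist_F[leg, idx]


@njit(cache=True)
def table_interp(tg, vals, x):
    """Piecewise-linear table lookup holding the end values."""
    n = tg.shape[0]
    if n == 0:
        return 0.0
    if x <= tg[0]:
        return vals[0]
    if x >= tg[n - 1]:
        return vals[n - 1]
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if tg[mid] <= x:
            lo = mid
        else:
            hi = mid
    w = (x - tg[lo]) / (tg[hi] - tg[lo])
    return vals[lo] * (1.0 - w) + vals[hi] * w


# ---- force / torque evaluation ----------------------------------------------

@njit(cache=True)
def _forces(t, y, feet, contact, P, gains, ctrl,
            pf_t, pf_rf, pf_ham, td_time, aux):
    """Per-leg torques, GRFs and geometry into ``aux`` (see module header)."""
    xh, yh = hip_xy(y[0], y[1], y[4], P[IRH])
    for k in range(NAUX):
        aux[k] = 0.0
    aux[8] = np.nan
    aux[9] = np.nan
    aux[14] = np.nan
    aux[15] = np.nan
    for leg in range(2):
        aux[12 + leg] = contact[leg]
        if contact[leg] == 0:
            continue
        aux[14 + leg] = feet[leg]
        fx = feet[leg]
        u = xh - fx
        l2 = u * u + yh * yh
        l = np.sqrt(l2)
        Fs = spring_force(l, P[IL0], P[IK])
        phih = hip_angle(y[4], xh, yh, fx)
        # d/dt of atan2(yh, u) with foot fixed
        ud = y[2] + P[IRH] * np.sin(y[4]) * y[5]
        vd = y[3] - P[IRH] * np.cos(y[4]) * y[5]
        phidoth = y[5] - (u * vd - yh * ud) / l2
        tau = 0.0
        if ctrl == CTRL_FMCH:
            Fpos = Fs if Fs > 0.0 else 0.0
            tau = P[IGFMCH] * Fpos * (P[IPHIH0] - phih)
        elif ctrl == CTRL_NMF or ctrl == CTRL_PREFLEX:
            rr = P[IRHO] * P[IR0]
            L_rf = P[ILMTU0] + rr * (phih - P[IPREF_RF])
            L_ham = P[ILMTU0] + rr * (P[IPREF_HAM] - phih)
            v_rf = rr * phidoth
            v_ham = -rr * phidoth
            if ctrl == CTRL_NMF:
                a_rf = y[6 + 2 * leg]
                a_ham = y[7 + 2 * leg]
            else:
                clock = t - td_time[leg]
                a_rf = table_interp(pf_t, pf_rf, clock)
                a_ham = table_interp(pf_t, pf_ham, clock)
            F_rf = a_rf * P[IFMAX] * fl_curve(L_rf, P[ILOPT], P[IW], P[IC]) \
                * fv_curve(v_rf, P[IVMAX], P[IKAP], P[INECC])
            F_ham = a_ham * P[IFMAX] * fl_curve(L_ham, P[ILOPT], P[IW], P[IC]) \
                * fv_curve(v_ham, P[IVMAX], P[IKAP], P[INECC])
            tau = (F_ham - F_rf) * P[IR0]
        gx, gy = grf_from(Fs, tau, xh, yh, fx)
        aux[0 + leg] = tau
        aux[2 + 2 * leg] = gx
        aux[3 + 2 * leg] = gy
        aux[6 + leg] = Fs
        aux[8 + leg] = phih
        aux[10 + leg] = phidoth
    return xh, yh


@njit(cache=True)
def _rhs(t, y, feet, contact, P, gains, ctrl,
         hist_t, hist_F, hist_n, pf_t, pf_rf, pf_ham, td_time, dy, aux):
    _forces(t, y, feet, contact, P, gains, ctrl, pf_t, pf_rf, pf_ham,
            td_time, aux)
    gx = aux[2] + aux[4]
    gy = aux[3] + aux[5]
    tau = aux[0] + aux[1]
    m = P[IM]
    dy[0] = y[2]
    dy[1] = y[3]
    dy[2] = gx / m
    dy[3] = gy / m - P[IG]
    dy[4] = y[5]
    dy[5] = (tau + P[IRH] * (gx * np.sin(y[4]) - gy * np.cos(y[4]))) / P[IJ]
    if ctrl == CTRL_NMF:
        tq = t - P[IDELTAP]
        for leg in range(2):
            Fdel = hist_lookup(hist_t, hist_F, hist_n, leg, tq)
            if Fdel < 0.0:
                Fdel = 0.0
            stim_rf = sat(P[ISTIM0] + gains[0] * Fdel, P[ISTIMLO], P[ISTIMHI])
            stim_ham = sat(P[ISTIM0] + gains[1] * Fdel, P[ISTIMLO], P[ISTIMHI])
            dy[6 + 2 * leg] = (stim_rf - y[6 + 2 * leg]) / P[ITECC]
            dy[7 + 2 * leg] = (stim_ham - y[7 + 2 * leg]) / P[ITECC]
    else:
        dy[6] = 0.0
        dy[7] = 0.0
        dy[8] = 0.0
        dy[9] = 0.0


@njit(cache=True)
def _rk4(t, y, s, feet, contact, P, gains, ctrl,
         hist_t, hist_F, hist_n, pf_t, pf_rf, pf_ham, td_time,
         ynew, k1, k2, k3, k4, ytmp, aux):
    _rhs(t, y, feet, contact, P, gains, ctrl, hist_t, hist_F, hist_n,
         pf_t, pf_rf, pf_ham, td_time, k1, aux)
    for i in range(NSTATE):
        ytmp[i] = y[i] + 0.5 * s * k1[i]
    _rhs(t + 0.5 * s, ytmp, feet, contact, P, gains, ctrl, hist_t, hist_F,
         hist_n, pf_t, pf_rf, pf_ham, td_time, k2, aux)
    for i in range(NSTATE):
        ytmp[i] = y[i] + 0.5 * s * k2[i]
    _rhs(t + 0.5 * s, ytmp, feet, contact, P, gains, ctrl, hist_t, hist_F,
         hist_n, pf_t, pf_rf, pf_ham, td_time, k3, aux)
    for i in range(NSTATE):
        ytmp[i] = y[i] + s * k3[i]
    _rhs(t + s, ytmp, feet, contact, P, gains, ctrl, hist_t, hist_F,
         hist_n, pf_t, pf_rf, pf_ham, td_time, k4, aux)
    for i in range(NSTATE):
        ynew[i] = y[i] + (s / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])


@njit(cache=True)
def _events(t, y, feet, contact, phase, stance, P, gains, ctrl,
            pf_t, pf_rf, pf_ham, td_time, ev, aux):
    """Event functions; every event triggers on a + -> - crossing.

    ev[0]: touchdown (single) / rear-leg takeoff (double)
    ev[1]: load loss of the leg that must stay loaded  -> fall
    ev[2]: mid-stance crossing (single support only)
    ev[3]: hip height floor   -> fall
    ev[4]: trunk pitch guard  -> fall
    """
    xh, yh = _forces(t, y, feet, contact, P, gains, ctrl, pf_t, pf_rf,
                     pf_ham, td_time, aux)
    ev[0] = _BIG
    ev[1] = _BIG
    ev[2] = _BIG
    if phase == PH_SINGLE:
        ox, oy = vbla(y[2], y[3], P[IMU], P[IG])
        nrm = np.sqrt(ox * ox + oy * oy)
        if nrm > 0.0 and oy < 0.0:
            ev[0] = yh + P[IL0] * oy / nrm
        ev[1] = aux[3 + 2 * stance]
        ev[2] = feet[stance] - xh
    else:
        rear = stance
        front = 1 - stance
        ev[0] = aux[3 + 2 * rear]
        ev[1] = aux[3 + 2 * front]
    ev[3] = yh - P[IFALLY]
    ev[4] = P[IFALLPHI] - np.abs(y[4] - _HALFPI)


@njit(cache=True)
def integrate_segment(t0, y, phase, stance, feet, contact, td_time,
                      P, gains, ctrl,
                      hist_t, hist_F, hist_n,
                      pf_t, pf_rf, pf_ham,
                      t_max, rec_every,
                      rec_t, rec_y, rec_aux, rec_n):
    """Advance the walker from ``t0`` until the next event or ``t_max``.

    Mutates ``y`` (and the history buffers) in place and returns
    ``(event_code, fall_reason, t_event)``.  Foot bookkeeping for phase
    transitions is left to the caller.
    """
    h = P[IH]
    ynew = np.empty(NSTATE)
    ytrial = np.empty(NSTATE)
    k1 = np.empty(NSTATE)
    k2 = np.empty(NSTATE)
    k3 = np.empty(NSTATE)
    k4 = np.empty(NSTATE)
    aux = np.empty(NAUX)
    ev_prev = np.empty(5)
    ev_new = np.empty(5)
    ev_ws = np.empty(5)

    t = t0
    _events(t, y, feet, contact, phase, stance, P, gains, ctrl,
            pf_t, pf_rf, pf_ham, td_time, ev_prev, aux)
    nrec = rec_t.shape[0]
    if nrec > 0 and rec_n[0] == 0:
        rec_t[0] = t
        for i in range(NSTATE):
            rec_y[0, i] = y[i]
        for i in range(NAUX):
            rec_aux[0, i] = aux[i]
        rec_n[0] = 1

    step_count = 0
    while t < t_max:
        s = h if t + h <= t_max else t_max - t
        _rk4(t, y, s, feet, contact, P, gains, ctrl, hist_t, hist_F, hist_n,
             pf_t, pf_rf, pf_ham, td_time, ynew, k1, k2, k3, k4, ytrial, aux)
        tn = t + s
        ok = True
        for i in range(NSTATE):
            if not np.isfinite(ynew[i]):
                ok = False
        if not ok:
            return EV_NAN, FALL_NONE, t
        _events(tn, ynew, feet, contact, phase, stance, P, gains, ctrl,
                pf_t, pf_rf, pf_ham, td_time, ev_new, aux)

        best_ev = -1
        best_s = _BIG
        for iev in range(5):
            if ev_prev[iev] > 0.0 and ev_new[iev] <= 0.0:
                lo = 0.0
                hi = s
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    _rk4(t, y, mid, feet, contact, P, gains, ctrl, hist_t,
                         hist_F, hist_n, pf_t, pf_rf, pf_ham, td_time,
                         ytrial, k1, k2, k3, k4, ynew, aux)
                    # note: ytrial is output, ynew reused as workspace
                    _events(t + mid, ytrial, feet, contact, phase, stance, P,
                            gains, ctrl, pf_t, pf_rf, pf_ham, td_time, ev_ws,
                            aux)
                    if ev_ws[iev] <= 0.0:
                        hi = mid
                    else:
                        lo = mid
                if hi < best_s:
                    best_s = hi
                    best_ev = iev
        if best_ev >= 0:
            _rk4(t, y, best_s, feet, contact, P, gains, ctrl, hist_t, hist_F,
                 hist_n, pf_t, pf_rf, pf_ham, td_time, ynew, k1, k2, k3, k4,
                 ytrial, aux)
            for i in range(NSTATE):
                y[i] = ynew[i]
            t = t + best_s
            _events(t, y, feet, contact, phase, stance, P, gains, ctrl,
                    pf_t, pf_rf, pf_ham, td_time, ev_new, aux)
            for leg in range(2):
                F = aux[6 + leg] if contact[leg] == 1 else 0.0
                hist_write(hist_t, hist_F, hist_n, leg, t, F)
            if nrec > 0 and rec_n[0] < nrec:
                j = rec_n[0]
                rec_t[j] = t
                for i in range(NSTATE):
                    rec_y[j, i] = y[i]
                for i in range(NAUX):
                    rec_aux[j, i] = aux[i]
                rec_n[0] = j + 1
            if phase == PH_SINGLE:
                if best_ev == 0:
                    return EV_TOUCHDOWN, FALL_NONE, t
                if best_ev == 2:
                    return EV_MIDSTANCE, FALL_NONE, t
            else:
                if best_ev == 0:
                    return EV_TAKEOFF, FALL_NONE, t
            if best_ev == 1:
                return EV_FALL, FALL_UNLOADED, t
            if best_ev == 3:
                return EV_FALL, FALL_LOW_HIP, t
            return EV_FALL, FALL_PITCH, t

        # accept the step
        for i in range(NSTATE):
            y[i] = ynew[i]
        t = tn
        for i in range(5):
            ev_prev[i] = ev_new[i]
        for leg in range(2):
            F = aux[6 + leg] if contact[leg] == 1 else 0.0
            hist_write(hist_t, hist_F, hist_n, leg, t, F)
        step_count += 1
        if nrec > 0 and rec_every > 0 and step_count % rec_every == 0 \
                and rec_n[0] < nrec:
            j = rec_n[0]
            rec_t[j] = t
            for i in range(NSTATE):
                rec_y[j, i] = y[i]
            for i in range(NAUX):
                rec_aux[j, i] = aux[i]
            rec_n[0] = j + 1
    return EV_TMAX, FALL_NONE, t
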