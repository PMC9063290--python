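"""Numba RK4 core for the adapting Ermentrout-type neuron.

Private module: the public surfaces are :mod:`tmas_adapt.neuron` (model
equations, states) and :mod:`tmas_adapt.simulate` (trajectories).  All
quantities here are in the membrane system of units: time in ms, voltage in
mV, currents in uA/cm^2.

The parameter vector layout (see ``NeuronParameters.as_vector``) is
[C_m, g_Na, g_K, g_L, g_Ca, g_M, g_AHP, E_Na, E_K, E_L, E_Ca, tau_w,
ca_sign].

Drive modes: 0 = gated offset carrier amp*(sin(2*pi*f_u*t)+1); 1 = gated
envelope (cycle-averaged carrier, amp inside on-phases); 2 = constant amp
(no gate; used for pre-adaptation and relaxation runs).
"""

import math

import numpy as np
from numba import njit

#: tolerated pre-clip gate excursion before it is flagged as integration error
GATE_TOL = 1.0e-6

#: runtime divergence guard on |V| (mV)
V_GUARD = 500.0

DRIVE_FULL = 0
DRIVE_ENVELOPE = 1
DRIVE_CONSTANT = 2


@njit(cache=True)
def rate_constants_nb(V):
    """Voltage-dependent transition rates (1/ms) with removable-singularity
    branches at V = -54 (alpha_m), -27 (beta_m) and -52 (alpha_n)."""
    x = V + 54.0
    if abs(x) < 1.0e-6:
        a_m = 0.32 * 4.0
    else:
        a_m = 0.32 * x / (1.0 - math.exp(-x / 4.0))
    x = V + 27.0
    if abs(x) < 1.0e-6:
        b_m = 0.28 * 5.0
    else:
        b_m = 0.28 * x / (math.exp(x / 5.0) - 1.0)
    a_h = 0.128 * math.exp(-(V + 50.0) / 18.0)
    b_h = 4.0 / (1.0 + math.exp(-(V + 27.0) / 5.0))
    x = V + 52.0
    if abs(x) < 1.0e-6:
        a_n = 0.032 * 5.0
    else:
        a_n = 0.032 * x / (1.0 - math.exp(-x / 5.0))
    b_n = 0.5 * math.exp(-(V + 57.0) / 40.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


@njit(cache=True)
def ionic_currents_nb(V, m, h, n, w, Ca, pp):
    """(I_Na, I_K, I_Ca, I_L, I_M, I_AHP) in uA/cm^2."""
    I_Na = pp[1] * m * m * m * h * (V - pp[7])
    I_K = pp[2] * n * n * n * n * (V - pp[8])
    I_Ca = pp[4] / (1.0 + math.exp(-(V + 25.0) / 5.0)) * (V - pp[10])
    I_L = pp[3] * (V - pp[9])
    I_M = pp[5] * w * (V - pp[8])
    I_AHP = pp[6] * Ca / (30.0 + Ca) * (V - pp[8])
    return I_Na, I_K, I_Ca, I_L, I_M, I_AHP


@njit(cache=True)
def derivatives_nb(V, m, h, n, w, Ca, I_ext, pp):
    a_m, b_m, a_h, b_h, a_n, b_n = rate_constants_nb(V)
    I_Na, I_K, I_Ca, I_L, I_M, I_AHP = ionic_currents_nb(V, m, h, n, w, Ca, pp)
    dV = (-I_Na - I_K - I_L - I_Ca - I_M - I_AHP + I_ext) / pp[0]
    dm = a_m * (1.0 - m) - b_m * m
    dh = a_h * (1.0 - h) - b_h * h
    dn = a_n * (1.0 - n) - b_n * n
    w_inf = 1.0 / (1.0 + math.exp(-(V + 20.0) / 5.0))
    dw = (w_inf - w) / pp[11]
    dCa = pp[12] * 0.002 * I_Ca - 0.0125 * Ca
    return dV, dm, dh, dn, dw, dCa


@njit(cache=True, inline="always")
def _drive(t, mode, amp, om_ms, rf_ms, dc):
    """Stimulus current at time t (ms); om_ms = 2*pi*f_u per ms."""
    if mode == DRIVE_CONSTANT:
        return amp
    if t <= 0.0:
        return 0.0
    u = t * rf_ms
    frac = u - math.floor(u)
    if frac == 0.0:
        frac = 1.0
    if frac > dc:
        return 0.0
    if mode == DRIVE_ENVELOPE:
        return amp
    return amp * (math.sin(om_ms * t) + 1.0)


@njit(cache=True)
def rk4_run(y0, pp, mode, amp, fu_hz, rf_hz, dc, n_steps, dt, stride):
    """Fixed-step RK4 trajectory.

    Returns (states, drive, excursion, diverged_at):
      states    -- (n_rec, 6) state samples, sample k at t = k*stride*dt
      drive     -- (n_rec,) stimulus current at the sample times
      excursion -- worst pre-clip overshoot of any gate outside [0, 1]
      diverged_at -- index of the first recorded sample with |V| >= 500 mV
                     (records beyond it are frozen), or -1
    """
    om_ms = 2.0 * math.pi * fu_hz * 1.0e-3
    rf_ms = rf_hz * 1.0e-3
    n_rec = n_steps // stride + 1
    states = np.empty((n_rec, 6))
    drive = np.empty(n_rec)
    V, m, h, n, w, Ca = y0[0], y0[1], y0[2], y0[3], y0[4], y0[5]
    states[0, 0] = V; states[0, 1] = m; states[0, 2] = h
    states[0, 3] = n; states[0, 4] = w; states[0, 5] = Ca
    drive[0] = _drive(0.0, mode, amp, om_ms, rf_ms, dc)
    excursion = 0.0
    diverged_at = -1
    j = 1
    for i in range(n_steps):
        t = i * dt
        I1 = _drive(t, mode, amp, om_ms, rf_ms, dc)
        I2 = _drive(t + 0.5 * dt, mode, amp, om_ms, rf_ms, dc)
        I3 = _drive(t + dt, mode, amp, om_ms, rf_ms, dc)
        d1 = derivatives_nb(V, m, h, n, w, Ca, I1, pp)
        d2 = derivatives_nb(V + 0.5 * dt * d1[0], m + 0.5 * dt * d1[1],
                            h + 0.5 * dt * d1[2], n + 0.5 * dt * d1[3],
                            w + 0.5 * dt * d1[4], Ca + 0.5 * dt * d1[5], I2, pp)
        d3 = derivatives_nb(V + 0.5 * dt * d2[0], m + 0.5 * dt * d2[1],
                            h + 0.5 * dt * d2[2], n + 0.5 * dt * d2[3],
                            w + 0.5 * dt * d2[4], Ca + 0.5 * dt * d2[5], I2, pp)
        d4 = derivatives_nb(V + dt * d3[0], m + dt * d3[1], h + dt * d3[2],
                            n + dt * d3[3], w + dt * d3[4], Ca + dt * d3[5],
                            I3, pp)
        V += dt / 6.0 * (d1[0] + 2.0 * d2[0] + 2.0 * d3[0] + d4[0])
        m += dt / 6.0 * (d1[1] + 2.0 * d2[1] + 2.0 * d3[1] + d4[1])
        h += dt / 6.0 * (d1[2] + 2.0 * d2[2] + 2.0 * d3[2] + d4[2])
        n += dt / 6.0 * (d1[3] + 2.0 * d2[3] + 2.0 * d3[3] + d4[3])
        w += dt / 6.0 * (d1[4] + 2.0 * d2[4] + 2.0 * d3[4] + d4[4])
        Ca += dt / 6.0 * (d1[5] + 2.0 * d2[5] + 2.0 * d3[5] + d4[5])
        # clip gates to [0, 1]; record the worst pre-clip excursion
        if m < 0.0:
            excursion = max(excursion, -m); m = 0.0
        elif m > 1.0:
            excursion = max(excursion, m - 1.0); m = 1.0
        if h < 0.0:
            excursion = max(excursion, -h); h = 0.0
        elif h > 1.0:
            excursion = max(excursion, h - 1.0); h = 1.0
        if n < 0.0:
            excursion = max(excursion, -n); n = 0.0
        elif n > 1.0:
            excursion = max(excursion, n - 1.0); n = 1.0
        if w < 0.0:
            excursion = max(excursion, -w); w = 0.0
        elif w > 1.0:
            excursion = max(excursion, w - 1.0); w = 1.0
        if Ca < 0.0:
            Ca = 0.0  # nonnegativity guard on the calcium variable
        if (i + 1) % stride == 0:
            states[j, 0] = V; states[j, 1] = m; states[j, 2] = h
            states[j, 3] = n; states[j, 4] = w; states[j, 5] = Ca
            drive[j] = _drive((i + 1) * dt, mode, amp, om_ms, rf_ms, dc)
            if diverged_at < 0 and (not math.isfinite(V) or abs(V) >= V_GUARD):
                diverged_at = j
            j += 1
        elif not math.isfinite(V) or abs(V) >= V_GUARD:
            # diverged between samples: freeze remaining records and stop
            if diverged_at < 0:
                diverged_at = j
            break
    if diverged_at >= 0:
        for k in range(j, n_rec):
            states[k] = states[j - 1]
            drive[k] = 0.0
    return states, drive, excursion, diverged_at
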