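"""Numba-compiled fixed-step RK4 integrators.

All integrators share the same conventions:

* classical 4th-order Runge-Kutta with a fixed step ``dt``;
* time-varying drives are supplied on a half-step grid ``I_half`` of
  length ``2*n_steps + 1`` (values at t_k and t_k + dt/2), so every RK4
  stage sees the exact drive value;
* conductance drives are supplied as ``G_half`` (the product g*s(t)) plus
  a reversal potential, entering the voltage equation as G*(v_rev - v);
* instantaneous charge injections are grid-aligned: ``jump_steps[i]`` is
  the step index at which the membrane potential jumps by ``jump_w[i]``
  (applied as a right limit, before the step is taken);
* threshold/spike times are localized by linear interpolation between the
  bracketing grid points;
* a non-finite state aborts the run; the caller raises with the time (and
  cell, for the network) at which integration failed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi


@njit(cache=True)
def lif_rk4(v0, tau, dt, n_steps, I_half, G_half, vrev, jump_steps, jump_w, reset):
    """Leaky integrate-and-fire: dv/dt = -v/tau + I(t) + G(t)*(vrev - v).

    With ``reset`` the state is reset to 0 at each upward crossing of the
    threshold 1; without it the trajectory continues (used for the peak
    response M_eps), though crossings are still recorded.

    Returns (v_out, spike_times, n_spikes, err_time); err_time < 0 means OK.
    """
    v_out = np.empty(n_steps + 1)
    max_sp = n_steps + jump_steps.size + 1
    spikes = np.empty(max_sp)
    nsp = 0
    v = v0
    jp = 0
    half = 0.5 * dt
    for k in range(n_steps + 1):
        while jp < jump_steps.size and jump_steps[jp] == k:
            v += jump_w[jp]
            jp += 1
            if v >= 1.0:
                if nsp < max_sp:
                    spikes[nsp] = k * dt
                    nsp += 1
                if reset:
                    v = 0.0
        v_out[k] = v
        if k == n_steps:
            break
        i0 = I_half[2 * k]
        i1 = I_half[2 * k + 1]
        i2 = I_half[2 * k + 2]
        g0 = G_half[2 * k]
        g1 = G_half[2 * k + 1]
        g2 = G_half[2 * k + 2]
        k1 = -v / tau + i0 + g0 * (vrev - v)
        y = v + half * k1
        k2 = -y / tau + i1 + g1 * (vrev - y)
        y = v + half * k2
        k3 = -y / tau + i1 + g1 * (vrev - y)
        y = v + dt * k3
        k4 = -y / tau + i2 + g2 * (vrev - y)
        v_new = v + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not math.isfinite(v_new):
            return v_out, spikes[:nsp], nsp, (k + 1) * dt
        if v < 1.0 <= v_new:
            alpha = (1.0 - v) / (v_new - v)
            if nsp < max_sp:
                spikes[nsp] = (k + alpha) * dt
                nsp += 1
            if reset:
                # restart from 0 for the remainder of the step (Euler tail)
                v_new = (1.0 - alpha) * dt * (i2 + g2 * vrev)
        v = v_new
    return v_out, spikes[:nsp], nsp, -1.0


@njit(cache=True)
def theta_rk4(theta0, tau, dt, n_steps, I_half, G_half, vrev, jump_steps, jump_w):
    """Theta model integrated in the phase variable (never in v).

    dtheta/dt = -cos(theta)/tau + 2*I*(1 + cos(theta))
                + G * (2*vrev*(1 + cos(theta)) - (1 + cos(theta)) - sin(theta))

    where the conductance term is the image of G*(v_rev - v) under
    v = (1 + tan(theta/2))/2; it is smooth through theta = pi.  theta is
    kept unwrapped; a spike is an upward crossing of pi + 2*pi*k.  Voltage
    jumps v -> v + w are applied through the coordinate change.
    """
    th_out = np.empty(n_steps + 1)
    max_sp = n_steps + jump_steps.size + 1
    spikes = np.empty(max_sp)
    nsp = 0
    th = theta0
    jp = 0
    half = 0.5 * dt
    for k in range(n_steps + 1):
        while jp < jump_steps.size and jump_steps[jp] == k:
            # wrap to (-pi, pi), map to v, jump, map back on the same branch
            thw = th - TWO_PI * math.floor((th + math.pi) / TWO_PI)
            v = 0.5 * (1.0 + math.tan(0.5 * thw))
            v += jump_w[jp]
            thw2 = 2.0 * math.atan(2.0 * v - 1.0)
            th = th + (thw2 - thw)
            jp += 1
        th_out[k] = th
        if k == n_steps:
            break
        i0 = I_half[2 * k]
        i1 = I_half[2 * k + 1]
        i2 = I_half[2 * k + 2]
        g0 = G_half[2 * k]
        g1 = G_half[2 * k + 1]
        g2 = G_half[2 * k + 2]

        c = math.cos(th)
        s = math.sin(th)
        k1 = -c / tau + 2.0 * i0 * (1.0 + c) + g0 * ((2.0 * vrev - 1.0) * (1.0 + c) - s)
        y = th + half * k1
        c = math.cos(y)
        s = math.sin(y)
        k2 = -c / tau + 2.0 * i1 * (1.0 + c) + g1 * ((2.0 * vrev - 1.0) * (1.0 + c) - s)
        y = th + half * k2
        c = math.cos(y)
        s = math.sin(y)
        k3 = -c / tau + 2.0 * i1 * (1.0 + c) + g1 * ((2.0 * vrev - 1.0) * (1.0 + c) - s)
        y = th + dt * k3
        c = math.cos(y)
        s = math.sin(y)
        k4 = -c / tau + 2.0 * i2 * (1.0 + c) + g2 * ((2.0 * vrev - 1.0) * (1.0 + c) - s)
        th_new = th + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not math.isfinite(th_new):
            return th_out, spikes[:nsp], nsp, (k + 1) * dt
        target = math.pi + TWO_PI * nsp_offset(theta0, nsp)
        while th < target <= th_new and nsp < max_sp:
            alpha = (target - th) / (th_new - th)
            spikes[nsp] = (k + alpha) * dt
            nsp += 1
            target = math.pi + TWO_PI * nsp_offset(theta0, nsp)
        th = th_new
    return th_out, spikes[:nsp], nsp, -1.0


@njit(cache=True)
def nsp_offset(theta0, nsp):
    # crossing targets are pi, 3*pi, ... relative to the starting branch
    base = math.floor((theta0 + math.pi) / TWO_PI)
    return base + nsp


@njit(cache=True, inline="always")
def _linoid(a, x, s):
    """a*x / (1 - exp(-x/s)), with the removable singularity at x = 0 filled."""
    if abs(x) < 1e-7:
        return a * s * (1.0 + 0.5 * x / s)
    return a * x / (1.0 - math.exp(-x / s))


@njit(cache=True, inline="always")
def _linoid_neg(a, x, s):
    """a*x / (exp(x/s) - 1), with the removable singularity at x = 0 filled."""
    if abs(x) < 1e-7:
        return a * s * (1.0 - 0.5 * x / s)
    return a * x / (math.exp(x / s) - 1.0)


@njit(cache=True, inline="always")
def hh_rates(v, model_id):
    """Gating rates (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n).

    model_id 0: Wang-Buzsaki fast-spiking interneuron (temperature factor
    phi = 5 on h and n is applied by the caller); model_id 1: reduced
    Traub-Miles pyramidal cell.  Sodium activation m is instantaneous
    (m = m_inf) in both models.
    """
    if model_id == 0:
        am = _linoid(0.1, v + 35.0, 10.0)
        bm = 4.0 * math.exp(-(v + 60.0) / 18.0)
        ah = 0.07 * math.exp(-(v + 58.0) / 20.0)
        bh = 1.0 / (1.0 + math.exp(-(v + 28.0) / 10.0))
        an = _linoid(0.01, v + 34.0, 10.0)
        bn = 0.125 * math.exp(-(v + 44.0) / 80.0)
    else:
        am = _linoid(0.32, v + 54.0, 4.0)
        bm = _linoid_neg(0.28, v + 27.0, 5.0)
        ah = 0.128 * math.exp(-(v + 50.0) / 18.0)
        bh = 4.0 / (1.0 + math.exp(-(v + 27.0) / 5.0))
        an = _linoid(0.032, v + 52.0, 5.0)
        bn = 0.5 * math.exp(-(v + 57.0) / 40.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True, inline="always")
def hh_deriv(v, m, h, n, I, g, vrev, gna, gk, gl, vna, vk, vl, phi, model_id, dyn_m):
    """State derivative of a WB/RTM cell.

    With ``dyn_m`` the sodium activation m is a state variable (the RTM
    convention); otherwise it is instantaneous, m = m_inf(v) (the WB
    convention), and dm/dt is reported as 0.
    """
    am, bm, ah, bh, an, bn = hh_rates(v, model_id)
    if dyn_m == 0:
        m = am / (am + bm)
        dm = 0.0
    else:
        dm = am * (1.0 - m) - bm * m
    dv = (
        gna * m * m * m * h * (vna - v)
        + gk * n * n * n * n * (vk - v)
        + gl * (vl - v)
        + I
        + g * (vrev - v)
    )
    dh = phi * (ah * (1.0 - h) - bh * h)
    dn = phi * (an * (1.0 - n) - bn * n)
    return dv, dm, dh, dn


@njit(cache=True)
def hh_rk4(
    v0,
    m0,
    h0,
    n0,
    model_id,
    dyn_m,
    gna,
    gk,
    gl,
    vna,
    vk,
    vl,
    phi,
    detect,
    dt,
    n_steps,
    I_half,
    G_half,
    vrev,
    jump_steps,
    jump_w,
):
    """Single-compartment Hodgkin-Huxley-type neuron (WB or RTM).

    Spike times are the upward crossings of the detection level ``detect``
    (0 mV by default), localized by linear interpolation.
    """
    v_out = np.empty(n_steps + 1)
    m_out = np.empty(n_steps + 1)
    h_out = np.empty(n_steps + 1)
    n_out = np.empty(n_steps + 1)
    max_sp = n_steps + jump_steps.size + 1
    spikes = np.empty(max_sp)
    nsp = 0
    v = v0
    m = m0
    h = h0
    n = n0
    jp = 0
    half = 0.5 * dt
    for k in range(n_steps + 1):
        while jp < jump_steps.size and jump_steps[jp] == k:
            vprev = v
            v += jump_w[jp]
            jp += 1
            if vprev < detect <= v and nsp < max_sp:
                spikes[nsp] = k * dt
                nsp += 1
        v_out[k] = v
        m_out[k] = m
        h_out[k] = h
        n_out[k] = n
        if k == n_steps:
            break
        i0 = I_half[2 * k]
        i1 = I_half[2 * k + 1]
        i2 = I_half[2 * k + 2]
        g0 = G_half[2 * k]
        g1 = G_half[2 * k + 1]
        g2 = G_half[2 * k + 2]
        kv1, km1, kh1, kn1 = hh_deriv(v, m, h, n, i0, g0, vrev, gna, gk, gl, vna, vk, vl, phi, model_id, dyn_m)
        kv2, km2, kh2, kn2 = hh_deriv(
            v + half * kv1, m + half * km1, h + half * kh1, n + half * kn1,
            i1, g1, vrev, gna, gk, gl, vna, vk, vl, phi, model_id, dyn_m
        )
        kv3, km3, kh3, kn3 = hh_deriv(
            v + half * kv2, m + half * km2, h + half * kh2, n + half * kn2,
            i1, g1, vrev, gna, gk, gl, vna, vk, vl, phi, model_id, dyn_m
        )
        kv4, km4, kh4, kn4 = hh_deriv(
            v + dt * kv3, m + dt * km3, h + dt * kh3, n + dt * kn3,
            i2, g2, vrev, gna, gk, gl, vna, vk, vl, phi, model_id, dyn_m
        )
        v_new = v + dt / 6.0 * (kv1 + 2.0 * kv2 + 2.0 * kv3 + kv4)
        m_new = m + dt / 6.0 * (km1 + 2.0 * km2 + 2.0 * km3 + km4)
        h_new = h + dt / 6.0 * (kh1 + 2.0 * kh2 + 2.0 * kh3 + kh4)
        n_new = n + dt / 6.0 * (kn1 + 2.0 * kn2 + 2.0 * kn3 + kn4)
        if not (math.isfinite(v_new) and math.isfinite(h_new) and math.isfinite(n_new)):
            return v_out, m_out, h_out, n_out, spikes[:nsp], nsp, (k + 1) * dt
        if v < detect <= v_new and nsp < max_sp:
            alpha = (detect - v) / (v_new - v)
            spikes[nsp] = (k + alpha) * dt
            nsp += 1
        v = v_new
        m = m_new
        h = h_new
        n = n_new
    return v_out, m_out, h_out, n_out, spikes[:nsp], nsp, -1.0


@njit(cache=True)
def _ping_deriv(
    y,
    dy,
    n_e,
    n_i,
    drive_e,
    g_ee,
    g_ie,
    g_ei,
    g_ii,
    vrev_e,
    vrev_i,
    g_tonic,
    v_tonic,
    tau_re,
    tau_de,
    tau_ri,
    tau_di,
):
    """Derivative of the flat PING state vector.

    Layout: E-cells [vE | mE | hE | nE | sE] (5*n_e entries, block-major)
    followed by I-cells [vI | hI | nI | sI] (4*n_i entries).  The RTM
    E-cells carry dynamic sodium activation m; the WB I-cells use
    m = m_inf.  With all-to-all connectivity and uniform per-synapse
    conductances, only the summed gating of each population enters any
    cell's equation.
    """
    oI = 5 * n_e
    SE = 0.0
    for j in range(n_e):
        SE += y[4 * n_e + j]
    SI = 0.0
    for i in range(n_i):
        SI += y[oI + 3 * n_i + i]
    gE_exc = g_ee * SE  # onto E-cells
    gE_inh = g_ie * SI
    gI_exc = g_ei * SE  # onto I-cells
    gI_inh = g_ii * SI
    for j in range(n_e):
        v = y[j]
        m = y[n_e + j]
        h = y[2 * n_e + j]
        n = y[3 * n_e + j]
        s = y[4 * n_e + j]
        # RTM pyramidal cell
        dv, dm, dh, dn = hh_deriv(v, m, h, n, drive_e[j], 0.0, 0.0, 100.0, 80.0, 0.1, 50.0, -100.0, -67.0, 1.0, 1, 1)
        dv += gE_exc * (vrev_e - v) + gE_inh * (vrev_i - v) + g_tonic * (v_tonic - v)
        ds = 0.5 * (1.0 + math.tanh(v / 10.0)) * (1.0 - s) / tau_re - s / tau_de
        dy[j] = dv
        dy[n_e + j] = dm
        dy[2 * n_e + j] = dh
        dy[3 * n_e + j] = dn
        dy[4 * n_e + j] = ds
    for i in range(n_i):
        v = y[oI + i]
        h = y[oI + n_i + i]
        n = y[oI + 2 * n_i + i]
        s = y[oI + 3 * n_i + i]
        # WB interneuron, no external drive
        dv, dm, dh, dn = hh_deriv(v, 0.0, h, n, 0.0, 0.0, 0.0, 35.0, 9.0, 0.1, 55.0, -90.0, -65.0, 5.0, 0, 0)
        dv += gI_exc * (vrev_e - v) + gI_inh * (vrev_i - v)
        ds = 0.5 * (1.0 + math.tanh(v / 10.0)) * (1.0 - s) / tau_ri - s / tau_di
        dy[oI + i] = dv
        dy[oI + n_i + i] = dh
        dy[oI + 2 * n_i + i] = dn
        dy[oI + 3 * n_i + i] = ds


@njit(cache=True)
def ping_rk4(
    y0,
    n_e,
    n_i,
    drive_e,
    dt,
    n_steps,
    g_ee,
    g_ie,
    g_ei,
    g_ii,
    vrev_e,
    vrev_i,
    g_tonic,
    v_tonic,
    tau_re,
    tau_de,
    tau_ri,
    tau_di,
    detect,
):
    """Integrate the all-to-all E-I network; record spikes only.

    Returns (spike_cells, spike_times, n_spikes, err_time, err_cell),
    where spike_cells are 0-based indices (E-cells 0..n_e-1, I-cells
    n_e..n_e+n_i-1).  err_time < 0 means the run completed.
    """
    nv = y0.size
    y = y0.copy()
    k1 = np.empty(nv)
    k2 = np.empty(nv)
    k3 = np.empty(nv)
    k4 = np.empty(nv)
    yt = np.empty(nv)
    n_cells = n_e + n_i
    max_sp = int(n_cells * (n_steps * dt * 0.5 + 20.0))
    spike_cells = np.empty(max_sp, dtype=np.int64)
    spike_times = np.empty(max_sp)
    nsp = 0
    oI = 5 * n_e
    v_old = np.empty(n_cells)
    half = 0.5 * dt
    for k in range(n_steps):
        for j in range(n_e):
            v_old[j] = y[j]
        for i in range(n_i):
            v_old[n_e + i] = y[oI + i]
        _ping_deriv(y, k1, n_e, n_i, drive_e, g_ee, g_ie, g_ei, g_ii, vrev_e, vrev_i, g_tonic, v_tonic, tau_re, tau_de, tau_ri, tau_di)
        for m in range(nv):
            yt[m] = y[m] + half * k1[m]
        _ping_deriv(yt, k2, n_e, n_i, drive_e, g_ee, g_ie, g_ei, g_ii, vrev_e, vrev_i, g_tonic, v_tonic, tau_re, tau_de, tau_ri, tau_di)
        for m in range(nv):
            yt[m] = y[m] + half * k2[m]
        _ping_deriv(yt, k3, n_e, n_i, drive_e, g_ee, g_ie, g_ei, g_ii, vrev_e, vrev_i, g_tonic, v_tonic, tau_re, tau_de, tau_ri, tau_di)
        for m in range(nv):
            yt[m] = y[m] + dt * k3[m]
        _ping_deriv(yt, k4, n_e, n_i, drive_e, g_ee, g_ie, g_ei, g_ii, vrev_e, vrev_i, g_tonic, v_tonic, tau_re, tau_de, tau_ri, tau_di)
        for m in range(nv):
            y[m] = y[m] + dt / 6.0 * (k1[m] + 2.0 * k2[m] + 2.0 * k3[m] + k4[m])
        for c in range(n_cells):
            v_new = y[c] if c < n_e else y[oI + (c - n_e)]
            if not math.isfinite(v_new):
                return spike_cells[:nsp], spike_times[:nsp], nsp, (k + 1) * dt, c
            if v_old[c] < detect <= v_new and nsp < max_sp:
                alpha = (detect - v_old[c]) / (v_new - v_old[c])
                spike_cells[nsp] = c
                spike_times[nsp] = (k + alpha) * dt
                nsp += 1
    return spike_cells[:nsp], spike_times[:nsp], nsp, -1.0, -1
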