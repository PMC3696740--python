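"""Euler-Maruyama integration kernels (numba-compiled).

The kernels advance the model state, detect debounced dominance
switches online, and optionally record decimated state snapshots and
peak traces. Switch detection uses strict inequality with the incumbent
retained on ties; a candidate switch is committed only once the new
leader has held its lead for ``dwell`` model time units, with the
switch timed at the first crossing.

In the space-free networks u_j is a firing rate and is clamped at 0:
noise cannot drive rates negative (a negative rate would let the
inhibition term q_k u_k act as excitation).

Status codes: 0 = ok, otherwise the 1-based step index at which a
non-finite value was detected.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# percept integer codes shared with the Python layer
L, R = 0, 1


@njit(cache=True)
def ring_kernel(
    u,
    q,
    I_ext,
    c2,
    s2,
    cx,
    sx,
    dx,
    kappa,
    beta,
    gamma,
    heaviside,
    tau,
    tau_m,
    dt,
    n_steps,
    noise_amp,
    seed,
    dwell,
    snap_stride,
    snaps_u,
    snaps_q,
    snap_times,
    peak_stride,
    peaks,
    peak_times,
    sw_times,
    sw_from,
):
    """Advance the ring field in place; returns (n_switches, status)."""
    np.random.seed(seed)
    n = u.shape[0]
    half = n // 2
    dt_tm = dt / tau_m
    dt_tau = dt / tau
    namp = noise_amp * math.sqrt(dt) / tau_m
    noisy = namp > 0.0
    deplete = beta > 0.0
    max_sw = sw_times.shape[0]
    n_snap = snaps_u.shape[0]
    n_peak = peaks.shape[0]
    dom = -1  # undecided
    cand = -1
    cand_t = 0.0
    n_sw = 0
    for i in range(n_steps):
        # separable convolution: cos(2(x-y)) = c2 c2' + s2 s2'
        A = 0.0
        B = 0.0
        if heaviside:
            if deplete:
                for j in range(n):
                    if u[j] >= kappa:
                        A += c2[j] * q[j]
                        B += s2[j] * q[j]
                        q[j] += dt_tau * (1.0 - q[j] - beta * q[j])
                    else:
                        q[j] += dt_tau * (1.0 - q[j])
            else:
                for j in range(n):
                    if u[j] >= kappa:
                        A += c2[j] * q[j]
                        B += s2[j] * q[j]
        else:
            for j in range(n):
                fj = 1.0 / (1.0 + math.exp(-gamma * (u[j] - kappa)))
                qf = q[j] * fj
                A += c2[j] * qf
                B += s2[j] * qf
                if deplete:
                    q[j] += dt_tau * (1.0 - q[j] - beta * qf)
        A *= dx
        B *= dx
        e1 = 0.0
        e2 = 0.0
        if noisy:
            e1 = np.random.normal() * namp
            e2 = np.random.normal() * namp
        pL = -1.0e300
        for j in range(half):
            u[j] += dt_tm * (A * c2[j] + B * s2[j] + I_ext[j] - u[j]) + e1 * cx[j] + e2 * sx[j]
            if u[j] > pL:
                pL = u[j]
        pR = -1.0e300
        for j in range(half, n):
            u[j] += dt_tm * (A * c2[j] + B * s2[j] + I_ext[j] - u[j]) + e1 * cx[j] + e2 * sx[j]
            if u[j] > pR:
                pR = u[j]
        t = (i + 1) * dt
        if i % 1000 == 0 and not math.isfinite(u[0] + q[0]):
            return n_sw, i + 1
        # online debounced dominance detection
        lead = dom
        if pR > pL:
            lead = R
        elif pL > pR:
            lead = L
        if dom == -1:
            dom = lead
        elif lead == dom:
            cand = -1
        elif lead != -1:
            if cand == lead:
                if t - cand_t >= dwell and n_sw < max_sw:
                    sw_times[n_sw] = cand_t
                    sw_from[n_sw] = dom
                    n_sw += 1
                    dom = cand
                    cand = -1
            else:
                cand = lead
                cand_t = t
        if snap_stride > 0 and i % snap_stride == 0:
            k = i // snap_stride
            if k < n_snap:
                for j in range(n):
                    snaps_u[k, j] = u[j]
                    snaps_q[k, j] = q[j]
                snap_times[k] = t
        if peak_stride > 0 and i % peak_stride == 0:
            k = i // peak_stride
            if k < n_peak:
                peaks[k, 0] = pL
                peaks[k, 1] = pR
                peak_times[k] = t
    return n_sw, 0


@njit(cache=True)
def reduced_kernel(
    state,
    IR,
    IL,
    beta,
    tau,
    dt,
    n_steps,
    noise_amp,
    seed,
    dwell,
    snap_stride,
    snaps,
    snap_times,
    sw_times,
    sw_from,
):
    """Two-population network; ``state`` = [uR, uL, qR, qL], updated in place."""
    np.random.seed(seed)
    uR, uL, qR, qL = state[0], state[1], state[2], state[3]
    dt_tau = dt / tau
    namp = noise_amp * math.sqrt(dt)
    noisy = namp > 0.0
    max_sw = sw_times.shape[0]
    n_snap = snaps.shape[0]
    dom = -1
    cand = -1
    cand_t = 0.0
    n_sw = 0
    for i in range(n_steps):
        hR = 1.0 if IR - qL * uL >= 0.0 else 0.0
        hL = 1.0 if IL - qR * uR >= 0.0 else 0.0
        qR += dt_tau * (1.0 - qR - beta * uR * qR)
        qL += dt_tau * (1.0 - qL - beta * uL * qL)
        uR += dt * (hR - uR)
        uL += dt * (hL - uL)
        if noisy:
            uR += np.random.normal() * namp
            uL += np.random.normal() * namp
            if uR < 0.0:  # rates are nonnegative
                uR = 0.0
            if uL < 0.0:
                uL = 0.0
        t = (i + 1) * dt
        if i % 10000 == 0 and not math.isfinite(uR + uL + qR + qL):
            return n_sw, i + 1
        lead = dom
        if uR > uL:
            lead = R
        elif uL > uR:
            lead = L
        if dom == -1:
            dom = lead
        elif lead == dom:
            cand = -1
        elif lead != -1:
            if cand == lead:
                if t - cand_t >= dwell and n_sw < max_sw:
                    sw_times[n_sw] = cand_t
                    sw_from[n_sw] = dom
                    n_sw += 1
                    dom = cand
                    cand = -1
            else:
                cand = lead
                cand_t = t
        if snap_stride > 0 and i % snap_stride == 0:
            k = i // snap_stride
            if k < n_snap:
                snaps[k, 0] = uR
                snaps[k, 1] = uL
                snaps[k, 2] = qR
                snaps[k, 3] = qL
                snap_times[k] = t
    state[0], state[1], state[2], state[3] = uR, uL, qR, qL
    return n_sw, 0


@njit(cache=True)
def tristable_kernel(
    u,
    q,
    I,
    beta,
    tau,
    dt,
    n_steps,
    noise_amp,
    seed,
    dwell,
    snap_stride,
    snaps,
    snap_times,
    sw_times,
    sw_from,
):
    """Three-population network; u, q are length-3 arrays updated in place."""
    np.random.seed(seed)
    dt_tau = dt / tau
    namp = noise_amp * math.sqrt(dt)
    noisy = namp > 0.0
    max_sw = sw_times.shape[0]
    n_snap = snaps.shape[0]
    dom = -1
    cand = -1
    cand_t = 0.0
    n_sw = 0
    h = np.empty(3)
    for i in range(n_steps):
        for j in range(3):
            inh = 0.0
            for k in range(3):
                if k != j:
                    inh += q[k] * u[k]
            h[j] = 1.0 if I - inh >= 0.0 else 0.0
        for j in range(3):
            q[j] += dt_tau * (1.0 - q[j] - beta * u[j] * q[j])
            u[j] += dt * (h[j] - u[j])
            if noisy:
                u[j] += np.random.normal() * namp
                if u[j] < 0.0:  # rates are nonnegative
                    u[j] = 0.0
        t = (i + 1) * dt
        if i % 10000 == 0 and not math.isfinite(u[0] + u[1] + u[2]):
            return n_sw, i + 1
        # strict-max leader; ties retain the incumbent
        lead = 0
        if u[1] > u[lead]:
            lead = 1
        if u[2] > u[lead]:
            lead = 2
        is_strict = True
        for j in range(3):
            if j != lead and u[j] >= u[lead]:
                is_strict = False
        if not is_strict:
            lead = dom
        if dom == -1:
            dom = lead
        elif lead == dom:
            cand = -1
        elif lead != -1:
            if cand == lead:
                if t - cand_t >= dwell and n_sw < max_sw:
                    sw_times[n_sw] = cand_t
                    sw_from[n_sw] = dom
                    n_sw += 1
                    dom = cand
                    cand = -1
            else:
                cand = lead
                cand_t = t
        if snap_stride > 0 and i % snap_stride == 0:
            k = i // snap_stride
            if k < n_snap:
                for j in range(3):
                    snaps[k, j] = u[j]
                    snaps[k, 3 + j] = q[j]
                snap_times[k] = t
    return n_sw, 0
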