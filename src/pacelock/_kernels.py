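"""Numba kernels for phase-equation integration.

Everything here operates on plain arrays so it can be jitted; the public
classes in :mod:`pacelock.phase` and :mod:`pacelock.network` convert their
objects to these arrays.  Phase-response curves are passed as dense lookup
tables sampled at K equidistant nodes k/K on [0, 1) and evaluated by periodic
linear interpolation.

Units: intrinsic rate in spikes/s, current in pA, Z in cycles/pC, time step
in s, so current * Z * dt is a phase increment in cycles (pA * s = pC).
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True, inline="always")
def _interp_periodic(table, x):
    K = table.shape[0]
    u = (x - np.floor(x)) * K
    i = int(u)
    if i >= K:  # floating-point edge when x is within 1 ulp below an integer
        i = K - 1
    frac = u - i
    j = i + 1
    if j == K:
        j = 0
    return table[i] * (1.0 - frac) + table[j] * frac


@njit(cache=True)
def run_current_train(f0, table, current, dt, noise_step_sd, seed):
    """Integrate dphi/dt = f0 + I(t) Z(phi) with per-step Gaussian phase noise.

    ``current`` holds one sample per Euler step (piecewise-constant drive).
    Spikes are emitted when phi crosses 1; the crossing time is linearly
    interpolated within the step and phi is reset by -1 (overshoot kept).
    Returns the spike times in seconds.
    """
    np.random.seed(seed)
    n = current.shape[0]
    max_spk = int(f0 * n * dt * 3.0) + 64
    out = np.empty(max_spk)
    m = 0
    x = 0.0
    for k in range(n):
        z = _interp_periodic(table, x)
        dx = (f0 + current[k] * z) * dt
        if noise_step_sd > 0.0:
            dx += noise_step_sd * np.random.normal()
        xn = x + dx
        if xn >= 1.0:
            if m < max_spk:
                frac = (1.0 - x) / dx
                out[m] = (k + frac) * dt
                m += 1
            xn -= 1.0
        x = xn
    return out[:m]


@njit(cache=True)
def return_map_points(f0, table, f_stim, A, harmonic, dt, phi_prev, max_time):
    """Deterministic stimulus phase at the next spike for each start phase.

    For each entry of ``phi_prev`` the neuron phase starts at 0 and the
    stimulus clock at phi_prev; integration runs until the neuron phase
    crosses 1.  Entries that fail to spike within ``max_time`` are NaN.
    """
    n = phi_prev.shape[0]
    out = np.empty(n)
    for i in range(n):
        p0 = phi_prev[i]
        x = 0.0
        t = 0.0
        t_cross = -1.0
        while t < max_time:
            cur = A * np.sin(TWO_PI * harmonic * (f_stim * t + p0))
            dx = (f0 + cur * _interp_periodic(table, x)) * dt
            xn = x + dx
            if xn >= 1.0:
                t_cross = t + dt * (1.0 - x) / dx
                break
            x = xn
            t += dt
        if t_cross < 0.0:
            out[i] = np.nan
        else:
            out[i] = (p0 + f_stim * t_cross) % 1.0
    return out


@njit(cache=True)
def iterate_map(disp_table, noise_sd, n_samples, burn_in, seed, phi0):
    """Iterate phi <- phi + D(phi) + noise (mod 1) on a tabulated displacement.

    ``disp_table`` holds the wrapped displacement phi_next - phi_prev at the
    map's grid nodes; between nodes it is interpolated periodically.
    """
    np.random.seed(seed)
    out = np.empty(n_samples)
    x = phi0 % 1.0
    for k in range(burn_in + n_samples):
        d = _interp_periodic(disp_table, x)
        x = x + d
        if noise_sd > 0.0:
            x += noise_sd * np.random.normal()
        x %= 1.0
        if k >= burn_in:
            out[k - burn_in] = x
    return out


@njit(cache=True)
def network_sim(f0s, tables, sig_steps, biases, indptr, targets,
                decay, syn_gain, q_mean, q_sd, A, f_stim, dt, n_steps,
                seed, barrage_rates, use_synapses, use_barrage, max_spikes):
    """Euler integration of a population of phase neurons with inhibitory
    conductance synapses (instantaneous rise, exponential decay).

    tables: (N, K) per-neuron iPRC lookup tables.
    indptr/targets: CSR adjacency by presynaptic source (directed edges).
    syn_gain: pA per nS of conductance (E_rev - V_nominal, negative for
    inhibition).  Quantal peaks ~ N(q_mean, q_sd) truncated at 0 nS.
    barrage_rates: per-neuron Poisson event rate (events/s) used when
    ``use_barrage``; the events draw the same quantal distribution.

    Returns (spike_times (N, max_spikes), counts (N,), n_events (N,)) where
    n_events counts inhibitory events received per neuron.
    """
    np.random.seed(seed)
    N = f0s.shape[0]
    x = np.zeros(N)
    g = np.zeros(N)
    spk = np.zeros((N, max_spikes))
    counts = np.zeros(N, np.int64)
    n_events = np.zeros(N, np.int64)
    fired = np.empty(N, np.int64)
    for kstep in range(n_steps):
        t = kstep * dt
        istim = A * np.sin(TWO_PI * f_stim * t)
        nf = 0
        for i in range(N):
            z = _interp_periodic(tables[i], x[i])
            cur = istim + biases[i] + syn_gain * g[i]
            dx = (f0s[i] + cur * z) * dt
            if sig_steps[i] > 0.0:
                dx += sig_steps[i] * np.random.normal()
            xn = x[i] + dx
            if xn >= 1.0:
                c = counts[i]
                if c < max_spikes:
                    if dx > 0.0:
                        spk[i, c] = t + dt * (1.0 - x[i]) / dx
                    else:
                        spk[i, c] = t
                    counts[i] = c + 1
                xn -= 1.0
                fired[nf] = i
                nf += 1
            x[i] = xn
        for i in range(N):
            g[i] *= decay
        if use_synapses:
            for s in range(nf):
                i = fired[s]
                for e in range(indptr[i], indptr[i + 1]):
                    j = targets[e]
                    q = q_mean + q_sd * np.random.normal()
                    if q < 0.0:
                        q = 0.0
                    g[j] += q
                    n_events[j] += 1
        if use_barrage:
            for i in range(N):
                m = np.random.poisson(barrage_rates[i] * dt)
                for _ in range(m):
                    q = q_mean + q_sd * np.random.normal()
                    if q < 0.0:
                        q = 0.0
                    g[i] += q
                    n_events[i] += 1
    return spk, counts, n_events
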