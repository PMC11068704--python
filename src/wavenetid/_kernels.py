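"""Numba-compiled right-hand sides and the explicit-Euler integration loop.

Each model is identified by an integer code; parameters travel as a flat
float64 vector whose layout is fixed by :mod:`wavenetid.neuron_models`.
Multiplicative parameter noise is applied per step from a pre-drawn array of
uniform deviates, so integration stays deterministic for a given seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

ML = 0
FHN = 1
FHN3D = 2
WANG = 3


@njit(cache=True)
def tensor_products(atoms, sel, out):
    """Fill ``out[j] = prod_i atoms[i, sel[j, i], :]`` row by row.

    ``atoms`` is (N_I, n_atoms, n); ``out`` is (J, n).  Single fused pass so
    the chunk is written once and atom rows stay cache-resident.
    """
    n_inputs = atoms.shape[0]
    n = atoms.shape[2]
    for j in range(sel.shape[0]):
        row = out[j]
        a0 = atoms[0, sel[j, 0]]
        if n_inputs == 1:
            for m in range(n):
                row[m] = a0[m]
            continue
        a1 = atoms[1, sel[j, 1]]
        for m in range(n):
            row[m] = a0[m] * a1[m]
        for i in range(2, n_inputs):
            ai = atoms[i, sel[j, i]]
            for m in range(n):
                row[m] *= ai[m]


@njit(cache=True)
def rhs_into(code, y, i_app, p, out):
    if code == ML:
        # p: C, g_L, g_Ca, g_K, V_L, V_Ca, V_K, V1, V2, V3, V4, phi
        v, w = y[0], y[1]
        minf = 0.5 * (1.0 + math.tanh((v - p[7]) / p[8]))
        winf = 0.5 * (1.0 + math.tanh((v - p[9]) / p[10]))
        lam = p[11] * math.cosh((v - p[9]) / (2.0 * p[10]))
        out[0] = (
            i_app
            - p[1] * (v - p[4])
            - p[2] * minf * (v - p[5])
            - p[3] * w * (v - p[6])
        ) / p[0]
        out[1] = lam * (winf - w)
    elif code == FHN:
        # p: a, gamma, eps
        v, w = y[0], y[1]
        out[0] = v * (v - p[0]) * (1.0 - v) - w + i_app
        out[1] = p[2] * (v - p[1] * w)
    elif code == FHN3D:
        # p: a, gamma, eps, mu, c, b
        v, w, yy = y[0], y[1], y[2]
        out[0] = v * (v - p[0]) * (1.0 - v) - w + yy + i_app
        out[1] = p[2] * (v - p[1] * w)
        out[2] = p[3] * (p[4] - p[5] * v - yy)
    else:
        # p: C, g_L, g_Na, g_K, E_L, E_Na, E_K, phi
        v, h, n = y[0], y[1], y[2]
        am = 0.1 * (v + 35.0)
        den = 1.0 - math.exp(-(v + 35.0) / 10.0)
        if abs(den) < 1e-12:
            am = 1.0  # limit of am/den at v = -35
        else:
            am = am / den
        bm = 4.0 * math.exp(-(v + 60.0) / 18.0)
        minf = am / (am + bm)
        ah = 0.07 * math.exp(-(v + 58.0) / 20.0)
        bh = 1.0 / (1.0 + math.exp(-(v + 28.0) / 10.0))
        an = 0.01 * (v + 34.0)
        denn = 1.0 - math.exp(-(v + 34.0) / 10.0)
        if abs(denn) < 1e-12:
            an = 0.1
        else:
            an = an / denn
        bn = 0.125 * math.exp(-(v + 44.0) / 80.0)
        out[0] = (
            i_app
            - p[1] * (v - p[4])
            - p[2] * minf**3 * h * (v - p[5])
            - p[3] * n**4 * (v - p[6])
        ) / p[0]
        out[1] = p[7] * (ah * (1.0 - h) - bh * h)
        out[2] = p[7] * (an * (1.0 - n) - bn * n)


@njit(cache=True)
def euler_loop(code, params, x0, i_app, dt, noise, noisy_idx, bound, states):
    """Explicit Euler; returns -1 on success, else the step index of blow-up.

    ``noise`` has shape (n_steps-1, len(noisy_idx)) of xi draws (may be
    (0, 0) when no noise is requested); noisy parameters become
    ``kappa * (1 + xi)`` freshly at every step.
    """
    n_steps = i_app.shape[0]
    n_state = x0.shape[0]
    p = params.copy()
    deriv = np.empty(n_state)
    for j in range(n_state):
        states[0, j] = x0[j]
    use_noise = noise.shape[0] > 0
    for m in range(1, n_steps):
        if use_noise:
            for q in range(noisy_idx.shape[0]):
                p[noisy_idx[q]] = params[noisy_idx[q]] * (1.0 + noise[m - 1, q])
        rhs_into(code, states[m - 1], i_app[m - 1], p, deriv)
        for j in range(n_state):
            val = states[m - 1, j] + dt * deriv[j]
            if not math.isfinite(val) or abs(val) > bound:
                return m
            states[m, j] = val
    return -1
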