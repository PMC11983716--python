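"""Compiled inner loops for the θ-space Langevin integrator.

The kernels are deliberately dumb: they take flat float64 arrays and the
pre-collapsed quadratic form of the potential (see
:func:`mslambda.alchemical_core.effective_quadratic_form`), plus a block of
pre-drawn unit-normal noise.  All randomness is generated outside the kernel
by a seeded :class:`numpy.random.Generator`, so trajectories are bit-stable
for a given seed regardless of compilation details.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["lam_from_theta", "grad_theta", "baoab_chunk"]


@njit(cache=False)
def lam_from_theta(theta, starts, stops, alpha, lam):
    """Per-site softmax of alpha*theta into preallocated ``lam``."""
    for s in range(starts.shape[0]):
        a, b = starts[s], stops[s]
        m = alpha * theta[a]
        for k in range(a + 1, b):
            v = alpha * theta[k]
            if v > m:
                m = v
        tot = 0.0
        for k in range(a, b):
            e = np.exp(alpha * theta[k] - m)
            lam[k] = e
            tot += e
        for k in range(a, b):
            lam[k] /= tot


@njit(cache=False)
def grad_theta(theta, lam, starts, stops, cvec, A, alpha, krest, grad):
    """∂V/∂θ with V = const + c·λ + ½λᵀAλ + ½ krest |θ|², into ``grad``."""
    n = theta.shape[0]
    # g = c + A @ lam
    for k in range(n):
        acc = cvec[k]
        for j in range(n):
            acc += A[k, j] * lam[j]
        grad[k] = acc
    for s in range(starts.shape[0]):
        a, b = starts[s], stops[s]
        dot = 0.0
        for k in range(a, b):
            dot += lam[k] * grad[k]
        for k in range(a, b):
            grad[k] = alpha * lam[k] * (grad[k] - dot) + krest * theta[k]


@njit(cache=False)
def baoab_chunk(
    theta,
    vel,
    noise,
    starts,
    stops,
    cvec,
    A,
    alpha,
    krest,
    dt,
    friction,
    kT,
    mass,
    save_interval,
    step_offset,
    frames,
    theta_frames,
    record_theta,
    n_saved0,
):
    """Integrate ``noise.shape[0]`` BAOAB steps; save λ every ``save_interval``.

    Splitting B-A-O-A-B; with friction = 0 the O-step is the identity and the
    scheme reduces to velocity Verlet.  Returns (n_saved, ok) where ok=False
    flags a non-finite coordinate (caller reports the offending step).
    """
    n = theta.shape[0]
    m_steps = noise.shape[0]
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1) / mass)
    lam = np.empty(n)
    f = np.empty(n)
    lam_from_theta(theta, starts, stops, alpha, lam)
    grad_theta(theta, lam, starts, stops, cvec, A, alpha, krest, f)
    n_saved = n_saved0
    half = 0.5 * dt
    for k in range(m_steps):
        for i in range(n):
            vel[i] -= half * f[i] / mass
            theta[i] += half * vel[i]
        for i in range(n):
            vel[i] = c1 * vel[i] + c2 * noise[k, i]
            theta[i] += half * vel[i]
        lam_from_theta(theta, starts, stops, alpha, lam)
        grad_theta(theta, lam, starts, stops, cvec, A, alpha, krest, f)
        for i in range(n):
            vel[i] -= half * f[i] / mass
        step = step_offset + k + 1
        if step % save_interval == 0:
            for i in range(n):
                frames[n_saved, i] = lam[i]
                if record_theta:
                    theta_frames[n_saved, i] = theta[i]
            n_saved += 1
        ok = True
        for i in range(n):
            if not np.isfinite(theta[i]):
                ok = False
        if not ok:
            return n_saved, step
    return n_saved, 0
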