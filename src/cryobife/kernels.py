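"""Numba-compiled inner loops: bead-model projection and the Metropolis chain."""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["render_projection", "render_batch", "run_metropolis_chain"]


@njit(cache=True)
def _render_into(out, pos, sigma, weight, R, shift_x, shift_y, px, box):
    """Rotate beads by R, project along z and stamp integrable 2D Gaussians.

    Pixel value = electrons * px^2 / (2 pi sigma^2) * exp(-d^2 / (2 sigma^2)),
    so the pixel sum approximates the total electron count.  The isotropic
    Gaussian is stamped separably (outer product of two 1D Gaussians), which
    keeps the exp count linear in the window size.  Returns the number of
    bead centers that landed outside the box (clipped).
    """
    n_beads = pos.shape[0]
    half = box / 2.0
    clipped = 0
    # electron-weighted centroid -> box center
    cx = 0.0
    cy = 0.0
    cz = 0.0
    wsum = 0.0
    for b in range(n_beads):
        cx += weight[b] * pos[b, 0]
        cy += weight[b] * pos[b, 1]
        cz += weight[b] * pos[b, 2]
        wsum += weight[b]
    cx /= wsum
    cy /= wsum
    cz /= wsum
    gx = np.empty(2 * box)
    gy = np.empty(2 * box)
    for b in range(n_beads):
        x = pos[b, 0] - cx
        y = pos[b, 1] - cy
        z = pos[b, 2] - cz
        rx = R[0, 0] * x + R[0, 1] * y + R[0, 2] * z
        ry = R[1, 0] * x + R[1, 1] * y + R[1, 2] * z
        # projection along the optical (z) axis: keep (rx, ry)
        u = rx / px + half + shift_x
        v = ry / px + half + shift_y
        if u < 0.0 or u >= box or v < 0.0 or v >= box:
            clipped += 1
        s = sigma[b] / px
        amp = weight[b] / (2.0 * np.pi * s * s)
        win = int(4.0 * s) + 1
        i_lo = max(0, int(v) - win)
        i_hi = min(box, int(v) + win + 1)
        j_lo = max(0, int(u) - win)
        j_hi = min(box, int(u) + win + 1)
        inv2s2 = 1.0 / (2.0 * s * s)
        for j in range(j_lo, j_hi):
            dx = j - u
            gx[j - j_lo] = np.exp(-dx * dx * inv2s2)
        for i in range(i_lo, i_hi):
            dy = i - v
            gy[i - i_lo] = amp * np.exp(-dy * dy * inv2s2)
        for i in range(i_lo, i_hi):
            gi = gy[i - i_lo]
            for j in range(j_lo, j_hi):
                out[i, j] += gi * gx[j - j_lo]
    return clipped


@njit(cache=True)
def _render_batch_impl(pos, sigma, weight, Rs, px, box, out):
    clipped = 0
    for k in range(Rs.shape[0]):
        clipped += _render_into(out[k], pos, sigma, weight, Rs[k], 0.0, 0.0, px, box)
    return clipped


def render_projection(pos, sigma, weight, R, px, box, shift=(0.0, 0.0)):
    """Single projection image (float64, rows = y, cols = x)."""
    out = np.zeros((box, box), dtype=np.float64)
    clipped = _render_into(
        out,
        np.ascontiguousarray(pos, dtype=np.float64),
        np.ascontiguousarray(sigma, dtype=np.float64),
        np.ascontiguousarray(weight, dtype=np.float64),
        np.ascontiguousarray(R, dtype=np.float64),
        float(shift[0]),
        float(shift[1]),
        float(px),
        int(box),
    )
    return out, clipped


def render_batch(pos, sigma, weight, Rs, px, box):
    """Projections for a stack of rotation matrices ``Rs`` of shape (n, 3, 3)."""
    Rs = np.ascontiguousarray(Rs, dtype=np.float64)
    out = np.zeros((Rs.shape[0], box, box), dtype=np.float64)
    _render_batch_impl(
        np.ascontiguousarray(pos, dtype=np.float64),
        np.ascontiguousarray(sigma, dtype=np.float64),
        np.ascontiguousarray(weight, dtype=np.float64),
        Rs,
        float(px),
        int(box),
        out,
    )
    return out


@njit(cache=True)
def run_metropolis_chain(A, seed, n_steps, step_half, init_lo, init_hi, guard, draws):
    """One random-walk Metropolis chain over gauge-fixed profiles.

    ``A[i, m] = exp(logL[i, m] - rowmax_i)`` are per-image likelihood factors
    (row-rescaled; the rescaling is a G-independent constant).  Per step: pick
    a node uniformly, perturb by dg ~ U[-step_half, step_half], re-center to
    sum(G) = 0, and accept on the log-posterior difference.  The posterior is

        sum_i log(sum_m A[i,m] exp(-G_m)) - I log(sum_m exp(-G_m))
        - 2 log(max(Gsq, guard)),

    with Gsq the sum of squared successive differences (smoothness prior).
    Every post-step state is stored in ``draws`` (n_steps, M).  Returns the
    acceptance rate.
    """
    np.random.seed(seed)
    I, M = A.shape
    G = np.empty(M)
    for m in range(M):
        G[m] = init_lo + (init_hi - init_lo) * np.random.random()
    G -= G.mean()

    def _log_target(Gv):
        q = np.exp(-Gv)
        total = 0.0
        qsum = 0.0
        for m in range(M):
            qsum += q[m]
        for i in range(I):
            s = 0.0
            for m in range(M):
                s += A[i, m] * q[m]
            total += np.log(s)
        total -= I * np.log(qsum)
        gsq = 0.0
        for m in range(M - 1):
            d = Gv[m + 1] - Gv[m]
            gsq += d * d
        if gsq < guard:
            gsq = guard
        return total - 2.0 * np.log(gsq)

    logpost = _log_target(G)
    accepted = 0
    Gp = np.empty(M)
    for step in range(n_steps):
        m = np.random.randint(M)
        dg = (np.random.random() * 2.0 - 1.0) * step_half
        shift = dg / M
        for k in range(M):
            Gp[k] = G[k] - shift
        Gp[m] += dg
        lp = _log_target(Gp)
        if np.log(np.random.random()) <= lp - logpost:
            for k in range(M):
                G[k] = Gp[k]
            logpost = lp
            accepted += 1
        for k in range(M):
            draws[step, k] = G[k]
    return accepted / n_steps
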