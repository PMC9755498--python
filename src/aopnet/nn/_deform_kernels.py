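"""Numba kernels for deformable-convolution bilinear sampling.

The sampling grid of a 3x3 deformable convolution reads, for every output
pixel and kernel tap, a bilinearly interpolated value at a learned
fractional position (zeros outside the input).  The gather (forward) and
scatter (input/offset gradients, backward) are the only operations in the
network that cannot be phrased as dense linear algebra, so they are
implemented as fused loops.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["deform_gather", "deform_scatter"]


@njit(cache=True, fastmath=True)
def deform_gather(xf, offy, offx):
    """Sample input ``xf`` (c, h, w) at the 9 offset taps.

    ``offy``/``offx`` have shape (9, h*w): per-tap fractional row/column
    offsets.  Returns cols (c, 9, h*w).
    """
    c, h, w = xf.shape
    hw = h * w
    cols = np.zeros((c, 9, hw), dtype=np.float32)
    for k in range(9):
        dy = k // 3 - 1
        dx = k % 3 - 1
        for p in range(hw):
            py = p // w + dy + offy[k, p]
            px = p % w + dx + offx[k, p]
            y0 = int(np.floor(py))
            x0 = int(np.floor(px))
            wy = py - y0
            wx = px - x0
            w00 = (1.0 - wy) * (1.0 - wx)
            w01 = (1.0 - wy) * wx
            w10 = wy * (1.0 - wx)
            w11 = wy * wx
            in00 = 0 <= y0 < h and 0 <= x0 < w
            in01 = 0 <= y0 < h and 0 <= x0 + 1 < w
            in10 = 0 <= y0 + 1 < h and 0 <= x0 < w
            in11 = 0 <= y0 + 1 < h and 0 <= x0 + 1 < w
            for ch in range(c):
                v = 0.0
                if in00:
                    v += w00 * xf[ch, y0, x0]
                if in01:
                    v += w01 * xf[ch, y0, x0 + 1]
                if in10:
                    v += w10 * xf[ch, y0 + 1, x0]
                if in11:
                    v += w11 * xf[ch, y0 + 1, x0 + 1]
                cols[ch, k, p] = v
    return cols


@njit(cache=True, fastmath=True)
def deform_scatter(xf, offy, offx, dcols, need_dx, need_doff):
    """Backward of :func:`deform_gather`.

    ``dcols`` is the gradient w.r.t. the sampled columns (c, 9, h*w).
    Returns (dx (c, h, w), doffy (9, h*w), doffx (9, h*w)); unneeded
    outputs are left at zero.
    """
    c, h, w = xf.shape
    hw = h * w
    dx_out = np.zeros((c, h, w), dtype=np.float32)
    doffy = np.zeros((9, hw), dtype=np.float32)
    doffx = np.zeros((9, hw), dtype=np.float32)
    for k in range(9):
        dy = k // 3 - 1
        dx = k % 3 - 1
        for p in range(hw):
            py = p // w + dy + offy[k, p]
            px = p % w + dx + offx[k, p]
            y0 = int(np.floor(py))
            x0 = int(np.floor(px))
            wy = py - y0
            wx = px - x0
            in00 = 0 <= y0 < h and 0 <= x0 < w
            in01 = 0 <= y0 < h and 0 <= x0 + 1 < w
            in10 = 0 <= y0 + 1 < h and 0 <= x0 < w
            in11 = 0 <= y0 + 1 < h and 0 <= x0 + 1 < w
            gy = 0.0
            gx = 0.0
            for ch in range(c):
                g = dcols[ch, k, p]
                v00 = xf[ch, y0, x0] if in00 else 0.0
                v01 = xf[ch, y0, x0 + 1] if in01 else 0.0
                v10 = xf[ch, y0 + 1, x0] if in10 else 0.0
                v11 = xf[ch, y0 + 1, x0 + 1] if in11 else 0.0
                if need_dx:
                    if in00:
                        dx_out[ch, y0, x0] += g * (1.0 - wy) * (1.0 - wx)
                    if in01:
                        dx_out[ch, y0, x0 + 1] += g * (1.0 - wy) * wx
                    if in10:
                        dx_out[ch, y0 + 1, x0] += g * wy * (1.0 - wx)
                    if in11:
                        dx_out[ch, y0 + 1, x0 + 1] += g * wy * wx
                if need_doff:
                    gy += g * ((1.0 - wx) * (v10 - v00) + wx * (v11 - v01))
                    gx += g * ((1.0 - wy) * (v01 - v00) + wy * (v11 - v10))
            doffy[k, p] = gy
            doffx[k, p] = gx
    return dx_out, doffy, doffx
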