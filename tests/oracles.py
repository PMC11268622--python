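"""Independent reference implementations used to cross-check the package.

Everything here is deliberately brute-force and shares no code path with
the implementation under test: dense matrices assembled entry by entry,
supersampled rasterization, grid-search minimizers and a plain
proximal-gradient (ISTA) loop in dense linear algebra.
"""

from __future__ import annotations

import numpy as np


def supersample_motion_kernel(length: float, angle_deg: float, oversample: int = 64) -> np.ndarray:
    """Rasterize the rotated unit-width rectangle by point sampling.

    Each candidate cell is covered with ``oversample x oversample`` sample
    points; a point is inside the blur region iff its rotated coordinates
    satisfy |u| <= length/2 and |v| <= 1/2.
    """
    t = np.deg2rad(angle_deg % 180.0)
    c, s = np.cos(t), np.sin(t)
    hx = (length * abs(c) + abs(s)) / 2.0
    hy = (length * abs(s) + abs(c)) / 2.0
    kx = int(np.floor(hx + 0.5 - 1e-9))
    ky = int(np.floor(hy + 0.5 - 1e-9))
    sub = (np.arange(oversample) + 0.5) / oversample - 0.5
    out = np.zeros((2 * ky + 1, 2 * kx + 1))
    for j in range(-ky, ky + 1):
        for i in range(-kx, kx + 1):
            xs = i + sub[None, :]
            ys = j + sub[:, None]
            u = xs * c + ys * s
            v = -xs * s + ys * c
            inside = (np.abs(u) <= length / 2.0) & (np.abs(v) <= 0.5)
            out[ky - j, i + kx] = inside.mean()
    while out.shape[0] > 1 and out[0].sum() == 0 and out[-1].sum() == 0:
        out = out[1:-1]
    while out.shape[1] > 1 and out[:, 0].sum() == 0 and out[:, -1].sum() == 0:
        out = out[:, 1:-1]
    return out / out.sum()


def dense_circulant_matrix(kernel: np.ndarray, shape: tuple) -> np.ndarray:
    """Assemble the full matrix of periodic convolution with ``kernel``."""
    n, m = shape
    kh, kw = kernel.shape
    ch, cw = kh // 2, kw // 2
    D = np.zeros((n * m, n * m))
    for i in range(n):
        for j in range(m):
            row = i * m + j
            for a in range(kh):
                for b in range(kw):
                    col = ((i - (a - ch)) % n) * m + ((j - (b - cw)) % m)
                    D[row, col] += kernel[a, b]
    return D


def dense_reflect_matrix(kernel: np.ndarray, shape: tuple) -> np.ndarray:
    """Matrix of reflect-boundary convolution, column by column from impulses,
    using np.pad plus an explicit convolution sum (no FFT, no shared code)."""
    n, m = shape
    kh, kw = kernel.shape
    ch, cw = kh // 2, kw // 2
    flipped = kernel[::-1, ::-1]
    D = np.zeros((n * m, n * m))
    for q in range(n * m):
        e = np.zeros(shape)
        e[q // m, q % m] = 1.0
        padded = np.pad(e, ((ch, ch), (cw, cw)), mode="reflect")
        out = np.zeros(shape)
        for i in range(n):
            for j in range(m):
                out[i, j] = np.sum(padded[i : i + kh, j : j + kw] * flipped)
        D[:, q] = out.ravel()
    return D


def ista_minimize(
    D: np.ndarray,
    y: np.ndarray,
    reg_weight: float,
    n_iters: int = 100_000,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Plain proximal gradient on 1/2||Dx - y||^2 + mu ||x||_1 with step 1/L,
    in dense linear algebra. The long-run iterate serves as the reference
    minimizer."""
    L = np.linalg.norm(D, 2) ** 2
    t = 1.0 / L
    x = y.copy() if x0 is None else x0.copy()
    M = np.eye(D.shape[1]) - t * (D.T @ D)
    b = t * (D.T @ y)
    thr = t * reg_weight
    for _ in range(n_iters):
        v = M @ x + b
        x = np.sign(v) * np.maximum(np.abs(v) - thr, 0.0)
    return x


def grid_search_prox_l1(v: float, threshold: float, lo=-3.0, hi=3.0, step=1e-4) -> float:
    """argmin_u 1/2 (u - v)^2 + threshold |u| over a dense 1-D grid."""
    grid = np.arange(lo, hi + step, step)
    vals = 0.5 * (grid - v) ** 2 + threshold * np.abs(grid)
    return float(grid[np.argmin(vals)])


def grid_search_prox_l2(v: np.ndarray, threshold: float, half_width=2.0, coarse=1e-2, fine=1e-4) -> np.ndarray:
    """argmin_u 1/2||u - v||^2 + threshold ||u||_2 for a 2-vector, by
    coarse-to-fine 2-D grid search."""
    v = np.asarray(v, dtype=float)

    def best_on(grid_x, grid_y):
        gx, gy = np.meshgrid(grid_x, grid_y, indexing="ij")
        vals = 0.5 * ((gx - v[0]) ** 2 + (gy - v[1]) ** 2) + threshold * np.hypot(gx, gy)
        idx = np.unravel_index(np.argmin(vals), vals.shape)
        return np.array([gx[idx], gy[idx]])

    c = best_on(
        np.arange(-half_width, half_width + coarse, coarse),
        np.arange(-half_width, half_width + coarse, coarse),
    )
    return best_on(
        np.arange(c[0] - 2 * coarse, c[0] + 2 * coarse + fine, fine),
        np.arange(c[1] - 2 * coarse, c[1] + 2 * coarse + fine, fine),
    )
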