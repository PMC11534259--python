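"""Numba kernels for non-Cartesian gridding, interpolation and the NUDFT oracle.

Sample k-space positions are passed in *fractional grid-cell coordinates*
(0..N-1 per axis, DC at N/2); kernels are looked up from a 1-D table sampled
uniformly on [0, width/2] with linear interpolation.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange


@njit(cache=True, inline="always")
def _kernel_lookup(table, half_width, dist):
    if dist >= half_width:
        return 0.0
    pos = dist / half_width * (table.shape[0] - 1)
    i = int(pos)
    frac = pos - i
    if i + 1 >= table.shape[0]:
        return table[-1]
    return table[i] * (1.0 - frac) + table[i + 1] * frac


@njit(cache=True)
def grid_to_cartesian(samples, weights, coords, shape, table, width):
    """Adjoint gridding: spread weighted samples onto a Cartesian grid."""
    nx, ny, nz = shape
    grid = np.zeros((nx, ny, nz), dtype=np.complex128)
    half = width / 2.0
    for s in range(coords.shape[0]):
        v = samples[s] * weights[s]
        ux, uy, uz = coords[s, 0], coords[s, 1], coords[s, 2]
        x0 = max(int(np.ceil(ux - half)), 0)
        x1 = min(int(np.floor(ux + half)), nx - 1)
        y0 = max(int(np.ceil(uy - half)), 0)
        y1 = min(int(np.floor(uy + half)), ny - 1)
        z0 = max(int(np.ceil(uz - half)), 0)
        z1 = min(int(np.floor(uz + half)), nz - 1)
        for ix in range(x0, x1 + 1):
            wx = _kernel_lookup(table, half, abs(ux - ix))
            if wx == 0.0:
                continue
            for iy in range(y0, y1 + 1):
                wy = _kernel_lookup(table, half, abs(uy - iy))
                if wy == 0.0:
                    continue
                wxy = wx * wy
                for iz in range(z0, z1 + 1):
                    wz = _kernel_lookup(table, half, abs(uz - iz))
                    if wz != 0.0:
                        grid[ix, iy, iz] += v * wxy * wz
    return grid


@njit(cache=True, parallel=True)
def interp_from_cartesian(grid, coords, table, width):
    """Forward interpolation: sample a Cartesian k-space grid at the coords."""
    nx, ny, nz = grid.shape
    out = np.zeros(coords.shape[0], dtype=np.complex128)
    half = width / 2.0
    for s in prange(coords.shape[0]):
        ux, uy, uz = coords[s, 0], coords[s, 1], coords[s, 2]
        x0 = max(int(np.ceil(ux - half)), 0)
        x1 = min(int(np.floor(ux + half)), nx - 1)
        y0 = max(int(np.ceil(uy - half)), 0)
        y1 = min(int(np.floor(uy + half)), ny - 1)
        z0 = max(int(np.ceil(uz - half)), 0)
        z1 = min(int(np.floor(uz + half)), nz - 1)
        acc = 0.0 + 0.0j
        for ix in range(x0, x1 + 1):
            wx = _kernel_lookup(table, half, abs(ux - ix))
            if wx == 0.0:
                continue
            for iy in range(y0, y1 + 1):
                wy = _kernel_lookup(table, half, abs(uy - iy))
                if wy == 0.0:
                    continue
                wxy = wx * wy
                for iz in range(z0, z1 + 1):
                    wz = _kernel_lookup(table, half, abs(uz - iz))
                    if wz != 0.0:
                        acc += grid[ix, iy, iz] * wxy * wz
        out[s] = acc
    return out


@njit(cache=True, parallel=True)
def nudft_forward(values, positions, kpoints):
    """Exact non-uniform DFT: sum_x v(x) exp(-2*pi*i k.x). Slow; oracle only."""
    out = np.zeros(kpoints.shape[0], dtype=np.complex128)
    for s in prange(kpoints.shape[0]):
        kx, ky, kz = kpoints[s, 0], kpoints[s, 1], kpoints[s, 2]
        acc = 0.0 + 0.0j
        for n in range(positions.shape[0]):
            phase = -2.0 * np.pi * (
                kx * positions[n, 0] + ky * positions[n, 1] + kz * positions[n, 2]
            )
            acc += values[n] * complex(np.cos(phase), np.sin(phase))
        out[s] = acc
    return out


@njit(cache=True, parallel=True)
def nudft_adjoint(samples, weights, kpoints, positions):
    """Exact adjoint NUDFT: sum_k w(k) S(k) exp(+2*pi*i k.x). Oracle only."""
    out = np.zeros(positions.shape[0], dtype=np.complex128)
    for n in prange(positions.shape[0]):
        px, py, pz = positions[n, 0], positions[n, 1], positions[n, 2]
        acc = 0.0 + 0.0j
        for s in range(kpoints.shape[0]):
            phase = 2.0 * np.pi * (
                kpoints[s, 0] * px + kpoints[s, 1] * py + kpoints[s, 2] * pz
            )
            acc += samples[s] * weights[s] * complex(np.cos(phase), np.sin(phase))
        out[n] = acc
    return out
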