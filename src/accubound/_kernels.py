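"""Euler–Maruyama inner loops, JIT-compiled when numba is available.

Both kernels consume a pre-drawn array of standard-normal increments so the
stream of random numbers — and hence every result — is identical with and
without numba.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def _jit(fn):
        return _njit(cache=False, fastmath=False)(fn)

except ImportError:  # pragma: no cover
    def _jit(fn):
        return fn


@_jit
def _polyval(coeffs, z):
    acc = 0.0
    for c in coeffs:
        acc = acc * z + c
    return acc


def _em_path(z0, g_coeffs, h_coeffs, dt, normals, noise_floor, out):
    """Integrate the path; ``out[0] = z0`` and ``out[k]`` after k steps.

    Returns the index of the first non-finite state, or -1 if all finite.
    """
    sq = np.sqrt(dt)
    z = z0
    out[0] = z
    for k in range(normals.shape[0]):
        g = _polyval(g_coeffs, z)
        h = _polyval(h_coeffs, z)
        if h < noise_floor:
            h = noise_floor
        z = z + g * dt + h * sq * normals[k]
        out[k + 1] = z
        if not np.isfinite(z):
            return k + 1
    return -1


def _first_passage(z0, g_coeffs, h_coeffs, dt, normals, noise_floor,
                   beta, band_halfwidth, use_band, k_offset):
    """Step until the crossing criterion holds.

    Returns (step_index, z_final, status): status 1 = crossed at
    ``k_offset + step`` steps, 0 = exhausted the normals without crossing,
    -1 = non-finite state at ``k_offset + step``.
    """
    sq = np.sqrt(dt)
    z = z0
    for k in range(normals.shape[0]):
        g = _polyval(g_coeffs, z)
        h = _polyval(h_coeffs, z)
        if h < noise_floor:
            h = noise_floor
        z = z + g * dt + h * sq * normals[k]
        if not np.isfinite(z):
            return k_offset + k + 1, z, -1
        if use_band:
            if abs(z - beta) < band_halfwidth:
                return k_offset + k + 1, z, 1
        else:
            if z >= beta:
                return k_offset + k + 1, z, 1
    return k_offset + normals.shape[0], z, 0


em_path = _jit(_em_path)
first_passage_kernel = _jit(_first_passage)
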