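"""Independent oracles used by the test suite.

Everything here is deliberately written by a different route than the
package (closed forms, direct-sum convolution, exact steady-state models)
so agreement between the two is meaningful.
"""

from __future__ import annotations

import numpy as np


def exact_vfa_invert(s_pd, s_t1, alpha_pd_rad, alpha_t1_rad, tr_ms):
    """Exact inversion of two equal-TR Ernst signals for (A, R1).

    With a shared E1 = exp(-TR R1) the two Ernst equations are linear in E1:
    E1 = (S1 sin a2 - S2 sin a1) / (S1 sin a2 cos a1 - S2 sin a1 cos a2).
    Closed form, no approximation: the oracle for quantifying the rational
    approximation's error.
    """
    s_pd = np.asarray(s_pd, dtype=float)
    s_t1 = np.asarray(s_t1, dtype=float)
    s1, c1 = np.sin(alpha_pd_rad), np.cos(alpha_pd_rad)
    s2, c2 = np.sin(alpha_t1_rad), np.cos(alpha_t1_rad)
    num = s_pd * s2 - s_t1 * s1
    den = s_pd * s2 * c1 - s_t1 * s1 * c2
    e1 = num / den
    r1 = -np.log(e1) / tr_ms * 1000.0  # s^-1
    a = s_pd * (1.0 - e1 * c1) / (s1 * (1.0 - e1))
    return a, r1


def afi_full_steady_state(alpha_rad, r1_s, tr1_ms, tr2_ms, scale=1000.0):
    """Exact interleaved two-TR steady-state signal pair (ideal spoiling).

    S1 ~ sin a (1 - E2 + (1 - E1) E2 cos a) / (1 - E1 E2 cos^2 a), and S2
    with the TR roles swapped.  The short-TR arccos inversion is only
    first-order exact against this model.
    """
    e1 = np.exp(-tr1_ms * r1_s / 1000.0)
    e2 = np.exp(-tr2_ms * r1_s / 1000.0)
    c = np.cos(alpha_rad)
    den = 1.0 - e1 * e2 * c ** 2
    s1 = scale * np.sin(alpha_rad) * (1.0 - e2 + (1.0 - e1) * e2 * c) / den
    s2 = scale * np.sin(alpha_rad) * (1.0 - e1 + (1.0 - e2) * e1 * c) / den
    return s1, s2


def brute_force_gaussian_1d(signal, sigma_vox, truncate=4.0):
    """Direct-sum truncated-Gaussian convolution (zero padding)."""
    radius = int(truncate * sigma_vox + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma_vox) ** 2)
    k /= k.sum()
    out = np.zeros_like(np.asarray(signal, dtype=float))
    n = len(signal)
    for i in range(n):
        acc = 0.0
        for j, kj in zip(x, k):
            idx = i + j
            if 0 <= idx < n:
                acc += kj * signal[idx]
        out[i] = acc
    return out


def brute_force_gaussian_nd(vol, sigma_vox, truncate=4.0):
    """Separable direct-sum Gaussian smoothing for small 3-D arrays."""
    out = np.asarray(vol, dtype=float).copy()
    for axis in range(out.ndim):
        out = np.apply_along_axis(
            brute_force_gaussian_1d, axis, out, sigma_vox, truncate
        )
    return out
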