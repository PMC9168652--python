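"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (double loops, quadrature,
textbook formulas) and shares no code path with the implementation it
checks.
"""

from __future__ import annotations

import numpy as np


def brute_contact_counts(d7, d8, a7, a8, threshold, angle_standard=None):
    """Frame-by-frame contact counting with explicit per-frame logic."""
    n_any = 0
    n_c8_only = 0
    for i in range(len(d7)):
        in7 = d7[i] < threshold
        in8 = d8[i] < threshold
        if angle_standard is not None:
            in7 = in7 and (a7[i] > angle_standard)
            in8 = in8 and (a8[i] > angle_standard)
        if in7 or in8:
            n_any += 1
        if in8 and not in7:
            n_c8_only += 1
    return n_any, n_c8_only


def spearman_no_ties(x, y):
    """Classic 1 - 6*sum(d^2)/(n(n^2-1)) formula; only valid without ties."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x)
    rx = np.empty(n)
    ry = np.empty(n)
    rx[np.argsort(x)] = np.arange(1, n + 1)
    ry[np.argsort(y)] = np.arange(1, n + 1)
    d = rx - ry
    return 1.0 - 6.0 * np.sum(d * d) / (n * (n * n - 1))


def pearson_on_midranks(x, y):
    """Mid-rank Spearman via an explicit rank assignment + textbook Pearson."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
            i = j + 1
        return ranks

    rx = midranks(x)
    ry = midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx * rx) * np.sum(ry * ry)))


def hct_integral_mc(x_i, rho_i, x_j, s_j, n_samples=2_000_000, seed=0):
    """Monte Carlo estimate of the pairwise descreening integral.

    (1/4pi) * integral of |y - x_i|^-4 over the ball of radius s_j
    around x_j, excluding |y - x_i| < rho_i.
    """
    rng = np.random.default_rng(seed)
    u = rng.random((n_samples, 3))
    # uniform in the ball around x_j
    r = s_j * np.cbrt(u[:, 0])
    cos_t = 2.0 * u[:, 1] - 1.0
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = 2.0 * np.pi * u[:, 2]
    y = np.asarray(x_j) + np.column_stack(
        [r * sin_t * np.cos(phi), r * sin_t * np.sin(phi), r * cos_t]
    )
    dist = np.linalg.norm(y - np.asarray(x_i), axis=1)
    integrand = np.where(dist >= rho_i, dist**-4, 0.0)
    vol = 4.0 / 3.0 * np.pi * s_j**3
    return vol * integrand.mean() / (4.0 * np.pi)


def two_sphere_sasa(R1, R2, d, probe):
    """Closed-form SASA of sphere 1 in a two-sphere system (expanded radii)."""
    a, b = R1 + probe, R2 + probe
    full = 4.0 * np.pi * a * a
    if d >= a + b:
        return full
    if d + a <= b:
        return 0.0
    h = a - (d * d + a * a - b * b) / (2.0 * d)
    return full - 2.0 * np.pi * a * h
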