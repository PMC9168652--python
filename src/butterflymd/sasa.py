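"""Numeric solvent-accessible surface area (Shrake–Rupley).

Deterministic golden-spiral quadrature on each atom's solvent-expanded
sphere; a test point is accessible if it lies outside every other
atom's expanded sphere.  Used for the nonpolar solvation term of the
per-residue decomposition, where an analytic pairwise-overlap SASA
would demand element-specific coefficient tables that add nothing to
the analysis.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sphere_points", "shrake_rupley"]


def sphere_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit-sphere points (golden-spiral lattice), deterministic."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n) + 0.5
    polar = np.arccos(1.0 - 2.0 * i / n)
    azim = np.pi * (1.0 + np.sqrt(5.0)) * i
    sp = np.sin(polar)
    return np.column_stack([sp * np.cos(azim), sp * np.sin(azim), np.cos(polar)])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom SASA in Å².

    Parameters
    ----------
    coords : (n, 3) array, Å
    radii : (n,) array of van der Waals radii, Å
    probe_radius : solvent probe radius, Å
    n_points : quadrature points per atom
    subset : optional indices; SASA is returned only for these atoms
        (all atoms still occlude).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(radii) != len(coords):
        raise ValueError("coords must be (n, 3) with matching radii")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    expanded = radii + probe_radius
    pts = sphere_points(n_points)
    targets = np.arange(len(coords)) if subset is None else np.asarray(subset, dtype=int)
    out = np.zeros(len(targets))
    for k, i in enumerate(targets):
        ri = expanded[i]
        shell = coords[i] + ri * pts
        d = np.linalg.norm(coords[i] - coords, axis=1)
        neigh = np.flatnonzero((d < ri + expanded) & (np.arange(len(coords)) != i))
        if neigh.size == 0:
            out[k] = 4.0 * np.pi * ri * ri
            continue
        diff = shell[:, None, :] - coords[neigh][None, :, :]
        buried = np.any(
            np.einsum("pnk,pnk->pn", diff, diff) < (expanded[neigh] ** 2)[None, :], axis=1
        )
        out[k] = 4.0 * np.pi * ri * ri * (np.count_nonzero(~buried) / n_points)
    return out
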