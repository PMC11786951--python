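"""Solvent-accessible surface area by the Shrake–Rupley method.

Each atom is inflated by the probe radius and sampled with a fixed
quasi-uniform point set (Fibonacci lattice, 960 points by default); a
point is accessible if it lies outside every other inflated atom. The
point set is deterministic, so repeated runs are bit-identical.

An optional ``point_filter`` callback lets callers additionally require
that the probe position of a surface point be reachable from bulk
solvent (used by the buriedness descriptor, which reuses the pocket
grid's flood-filled solvent region): without it, the sealed interior of
a closed cavity would count as accessible, because plain Shrake–Rupley
only tests local sphere overlap.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["fibonacci_sphere", "shrake_rupley"]

N_SPHERE_POINTS = 960


def fibonacci_sphere(n: int) -> np.ndarray:
    """(n, 3) quasi-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = N_SPHERE_POINTS,
    point_filter: Callable[[np.ndarray], np.ndarray] | None = None,
    atom_subset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom SASA in A^2.

    Parameters
    ----------
    coords : (n, 3) atom centers, A.
    radii : (n,) van der Waals radii, A.
    probe_radius : solvent probe radius, A (water: 1.4).
    n_points : sphere sample points per atom.
    point_filter : optional; maps an (m, 3) array of candidate probe
        positions to a boolean mask of points considered solvent-reachable.
    atom_subset : optional indices; areas are computed only for these atoms
        (all atoms still occlude). Other entries of the result are 0.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    sphere = fibonacci_sphere(n_points)
    inflated = radii + probe_radius
    tree = cKDTree(coords)
    max_r = inflated.max()
    areas = np.zeros(n)
    targets = range(n) if atom_subset is None else np.asarray(atom_subset, dtype=int)
    for i in targets:
        pts = coords[i] + inflated[i] * sphere
        # neighbors that could possibly occlude any sample point
        nbr = tree.query_ball_point(coords[i], r=inflated[i] + max_r)
        nbr = [j for j in nbr if j != i]
        free = np.ones(n_points, dtype=bool)
        if nbr:
            d = np.linalg.norm(pts[:, None, :] - coords[nbr][None, :, :], axis=2)
            free &= np.all(d >= inflated[nbr][None, :], axis=1)
        if point_filter is not None and free.any():
            free[free] = point_filter(pts[free])
        areas[i] = 4.0 * np.pi * inflated[i] ** 2 * free.sum() / n_points
    return areas
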