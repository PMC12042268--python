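"""Independent reference implementations used only to check the package.

These deliberately use different algorithms from the library: the
periodic Voronoi oracle intersects bisector half-spaces point by point
(vs the library's ghost-image Qhull tessellation), the contact oracle
enumerates all O(N^2) minimum-image pairs (vs the periodic k-d tree),
and the Gaussian-overlap oracle is the erf closed form.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial import ConvexHull, HalfspaceIntersection
from scipy.special import erfc

_SHIFTS = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float)


def brute_force_voronoi(points: np.ndarray, box: np.ndarray):
    """Periodic Voronoi by half-space intersection, one cell at a time.

    Returns ``(volumes, pair_areas)`` where ``pair_areas[(i, j)]`` (i <= j)
    is the total physical area shared by the cells of atoms i and j over
    all periodic images.
    """
    points = np.asarray(points, dtype=float)
    box = np.asarray(box, dtype=float)
    n = len(points)
    volumes = np.empty(n)
    pair_areas = {}
    for i in range(n):
        p = points[i]
        neighbours = []   # (atom index, image coordinate)
        for j in range(n):
            for s in _SHIFTS:
                q = points[j] + s * box
                if j == i and np.all(s == 0):
                    continue
                neighbours.append((j, q))
        halfspaces = []
        for _, q in neighbours:
            normal = q - p
            mid = 0.5 * (p + q)
            halfspaces.append(np.append(normal, -normal @ mid))
        hs = HalfspaceIntersection(np.asarray(halfspaces), p.copy())
        hull = ConvexHull(hs.intersections)
        volumes[i] = hull.volume
        verts = hs.intersections
        for (j, q), h in zip(neighbours, halfspaces):
            normal, offset = h[:3], h[3]
            scale = np.linalg.norm(normal)
            on_plane = np.abs(verts @ normal + offset) < 1e-8 * scale * box.max()
            face = verts[on_plane]
            if len(face) < 3:
                continue
            area = _polygon_area(face)
            if area > 1e-9:
                key = (min(i, j), max(i, j))
                # each physical face appears once from each owning cell
                pair_areas[key] = pair_areas.get(key, 0.0) + 0.5 * area
    return volumes, pair_areas


def _polygon_area(verts: np.ndarray) -> float:
    c = verts.mean(axis=0)
    rel = verts - c
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    ang = np.arctan2(rel @ vt[1], rel @ vt[0])
    rel = rel[np.argsort(ang)]
    u, v = rel @ vt[0], rel @ vt[1]
    return 0.5 * abs(np.dot(u, np.roll(v, -1)) - np.dot(v, np.roll(u, -1)))


def brute_force_contacts(top_coords, bot_coords, top_pos, bot_pos, box,
                         cutoff, n_positions):
    """Exhaustive minimum-image pair count into a position matrix."""
    values = np.zeros((n_positions, n_positions))
    box = np.asarray(box, dtype=float)
    for a in range(len(top_coords)):
        d = bot_coords - top_coords[a]
        d -= box * np.round(d / box)
        dist = np.linalg.norm(d, axis=1)
        for b in np.flatnonzero(dist <= cutoff):
            values[top_pos[a], bot_pos[b]] += 1
    return values


def gaussian_overlap(amplitude: float, d: float, sigma: float) -> float:
    """Overlap integral of two equal-weight Gaussians with means d apart.

    Each profile integrates to ``amplitude`` (per A^2); the overlap is
    amplitude * erfc(d / (2 sqrt(2) sigma)).
    """
    return amplitude * erfc(d / (2.0 * np.sqrt(2.0) * sigma))


def ar1_series(phi: float, n: int, rng: np.random.Generator,
               sigma: float = 1.0) -> np.ndarray:
    """Stationary AR(1) series x_t = phi x_{t-1} + eps_t."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma / np.sqrt(1 - phi**2))
    eps = rng.normal(0.0, sigma, size=n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x
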