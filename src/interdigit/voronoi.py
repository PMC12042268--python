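"""Periodic 3D Voronoi tessellation and the interfacial surface area.

Every lipid and water atom of a frame acts as a Voronoi generator.  The
bilayer midplane interface is the set of Voronoi faces shared by atom
pairs that belong to lipids of opposing leaflets; its total area divided
by the lateral box area A_xy is the normalized interfacial surface area

    nISA = ( sum_ij a_ij ) / A_xy ,

where a_ij is the area of the face common to the cells of atom i (top
leaflet) and atom j (bottom leaflet).  A flat, non-interdigitated
interface gives nISA = 1; corrugation of the midplane by chains
penetrating past z = 0 increases it.

Periodicity is handled by tessellating the generators together with
their 26 periodic images and then counting each physical (torus) face
exactly once: a face between two primary-image cells appears once in the
tessellation, while a face that crosses the boundary appears twice (once
from each side), so primary-ghost faces carry weight 1/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Voronoi, cKDTree

from .core import ChainIndexing, Frame, LeafletMap, Topology, wrap_coords

__all__ = [
    "VoronoiDiagram", "InterfaceMesh", "tessellate", "interface_mesh",
    "nisa", "nisa_series", "chain_contributions", "intensity_map",
    "export_mesh", "load_obj",
]

_JITTER_SEED = 0x5EED


def _deterministic_jitter(n: int, scale: float) -> np.ndarray:
    """Reproducible sub-resolution jitter keyed to atom index.

    Breaks exact degeneracies (cocircular/coplanar lattice generators)
    deterministically; `scale` is well below any physically meaningful
    distance.
    """
    rng = np.random.default_rng(_JITTER_SEED)
    return rng.uniform(-scale, scale, size=(n, 3))


def _polygon_area_3d(verts: np.ndarray) -> float:
    """Area of a planar convex polygon given unordered vertices."""
    if len(verts) < 3:
        return 0.0
    c = verts.mean(axis=0)
    rel = verts - c
    # plane basis from SVD; vertices of a Voronoi ridge are coplanar
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    e1, e2 = vt[0], vt[1]
    ang = np.arctan2(rel @ e2, rel @ e1)
    order = np.argsort(ang)
    u = rel[order] @ e1
    v = rel[order] @ e2
    return 0.5 * abs(np.dot(u, np.roll(v, -1)) - np.dot(v, np.roll(u, -1)))


@dataclass
class VoronoiDiagram:
    """Periodic tessellation of one frame.

    Faces are stored once per tessellation ridge that touches a
    primary-image generator; ``face_weight`` (1 or 1/2) converts ridge
    areas to physical torus-face areas, so any physical area is
    ``sum(face_area * face_weight)`` over the relevant faces.
    """

    n_generators: int
    generator_atoms: np.ndarray      # generator row -> atom index
    volumes: np.ndarray              # cell volume per generator, A^3
    face_atom_a: np.ndarray          # atom index of first owner
    face_atom_b: np.ndarray          # atom index of second owner
    face_area: np.ndarray            # geometric ridge area, A^2
    face_weight: np.ndarray          # 1.0 primary-primary, 0.5 primary-ghost
    face_central: np.ndarray         # atom whose primary-image cell owns the ridge
    face_vertices: list              # list of (k, 3) arrays, A
    box: np.ndarray

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())


@dataclass
class InterfaceMesh:
    """Voronoi faces shared by lipid atoms of opposing leaflets."""

    areas: np.ndarray        # physical (weighted) face areas, A^2
    atom_top: np.ndarray     # owning top-leaflet atom per face
    atom_bottom: np.ndarray  # owning bottom-leaflet atom per face
    vertices: list           # per-face polygon vertices, A
    box: np.ndarray

    @property
    def axy(self) -> float:
        return float(self.box[0] * self.box[1])

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def __len__(self):
        return len(self.areas)


def tessellate(frame: Frame, topology: Topology | None = None,
               include: np.ndarray | None = None,
               jitter: float = 1e-6) -> VoronoiDiagram:
    """Fully periodic 3D Voronoi tessellation of a frame.

    Parameters
    ----------
    frame : Frame
        Centered frame; coordinates are wrapped into the primary box.
    topology : Topology, optional
        When given, only lipid and water atoms act as generators.
    include : bool array, optional
        Explicit generator mask (overrides the topology-based default).
    jitter : float, Angstrom
        Deterministic degeneracy-breaking perturbation applied to all
        generators (see :func:`_deterministic_jitter`).

    Returns
    -------
    VoronoiDiagram
        Cell volumes sum to the box volume to ~1e-9 relative.
    """
    box = frame.box
    if include is None:
        if topology is not None:
            include = topology.is_lipid_atom() | topology.is_water_atom()
        else:
            include = np.ones(len(frame.coords), dtype=bool)
    gen_atoms = np.flatnonzero(include)
    pts = wrap_coords(frame.coords[gen_atoms], box)
    n = len(pts)
    if n < 2:
        raise ValueError("at least 2 non-degenerate generators are required")
    # coincident generators would produce empty cells; the jitter separates
    # them but the user should know the input is degenerate
    if len(np.unique(np.round(pts, 9), axis=0)) < n:
        warnings.warn("coincident generator points detected; separated by "
                      f"deterministic {jitter:g} A jitter", stacklevel=2)
    if jitter:
        pts = pts + _deterministic_jitter(len(frame.coords), jitter)[gen_atoms]

    shifts = np.array([(i, j, k)
                       for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)])
    shifts = np.vstack([[0, 0, 0], shifts[~np.all(shifts == 0, axis=1)]])
    all_pts = np.concatenate([pts + s * box for s in shifts])

    vor = Voronoi(all_pts)

    volumes = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region:
            raise RuntimeError("unbounded primary cell; box/ghost setup invalid")
        volumes[i] = ConvexHull(vor.vertices[region]).volume

    ridge_pts = vor.ridge_points
    touches_primary = ridge_pts.min(axis=1) < n
    fa, fb, farea, fw, fc, fverts = [], [], [], [], [], []
    for (p, q), rv in zip(ridge_pts[touches_primary],
                          np.asarray(vor.ridge_vertices, dtype=object)[touches_primary]):
        if -1 in rv:
            continue
        verts = vor.vertices[list(rv)]
        area = _polygon_area_3d(verts)
        if area <= 0.0:
            continue
        fa.append(gen_atoms[p % n])
        fb.append(gen_atoms[q % n])
        farea.append(area)
        fw.append(1.0 if (p < n and q < n) else 0.5)
        fc.append(gen_atoms[p % n] if p < n else gen_atoms[q % n])
        fverts.append(verts)
    return VoronoiDiagram(
        n_generators=n,
        generator_atoms=gen_atoms,
        volumes=volumes,
        face_atom_a=np.asarray(fa, dtype=int),
        face_atom_b=np.asarray(fb, dtype=int),
        face_area=np.asarray(farea, dtype=float),
        face_weight=np.asarray(fw, dtype=float),
        face_central=np.asarray(fc, dtype=int),
        face_vertices=fverts,
        box=box.copy(),
    )


def interface_mesh(diagram: VoronoiDiagram, leaflets: LeafletMap,
                   topology: Topology) -> InterfaceMesh:
    """Harvest the faces joining lipid atoms of opposing leaflets.

    Water-water and water-lipid faces are excluded (waters belong to no
    leaflet), as are faces between lipid atoms of the same leaflet.
    Each physical face is kept exactly once at its full geometric area:
    a face crossing the periodic boundary appears twice in the
    tessellation (once from each owning cell), and only the copy owned
    by the top-leaflet atom's primary cell is retained.  Vertex z
    coordinates are mapped to the centered representation (z in
    [-Lz/2, Lz/2)), so faces near the midplane form continuous polygons.
    Returns an empty mesh (with a warning) when the leaflets share no
    faces.
    """
    labels = leaflets.atom_labels(topology)
    la = labels[diagram.face_atom_a]
    lb = labels[diagram.face_atom_b]
    central_is_top = labels[diagram.face_central] == 1
    cross = (la * lb == -1) & ((diagram.face_weight == 1.0) | central_is_top)
    areas = diagram.face_area[cross]
    a = diagram.face_atom_a[cross]
    b = diagram.face_atom_b[cross]
    lz = diagram.box[2]
    verts = []
    for v, c in zip(diagram.face_vertices, cross):
        if c:
            w = v.copy()
            w[:, 2] = np.mod(w[:, 2] + lz / 2, lz) - lz / 2
            verts.append(w)
    # orient: atom_top from the top leaflet
    swap = la[cross] == -1
    atom_top = np.where(swap, b, a)
    atom_bottom = np.where(swap, a, b)
    if len(areas) == 0:
        warnings.warn("leaflets share no Voronoi faces; empty interface mesh "
                      "(nISA = 0)", stacklevel=2)
    return InterfaceMesh(areas=areas, atom_top=atom_top, atom_bottom=atom_bottom,
                         vertices=verts, box=diagram.box)


def nisa(mesh: InterfaceMesh) -> float:
    """Normalized interfacial surface area of one frame."""
    if mesh.axy == 0:
        raise ValueError("lateral box area is zero")
    return mesh.total_area / mesh.axy


def nisa_series(frames, topology: Topology, leaflets: LeafletMap,
                jitter: float = 1e-6):
    """Per-frame interfacial surface area table.

    Returns a DataFrame with columns frame, time (ns), isa (A^2),
    axy (A^2) and nisa; the trajectory-level value is the unweighted
    mean of the per-frame nISA (each frame uses its own instantaneous
    A_xy).
    """
    import pandas as pd

    rows = []
    for k, f in enumerate(frames):
        diagram = tessellate(f, topology, jitter=jitter)
        mesh = interface_mesh(diagram, leaflets, topology)
        rows.append({"frame": k, "time": f.time, "isa": mesh.total_area,
                     "axy": mesh.axy, "nisa": nisa(mesh)})
    return pd.DataFrame(rows)


def chain_contributions(mesh: InterfaceMesh, chains: ChainIndexing,
                        n_atoms: int) -> dict:
    """Fraction of the interfacial area by owner-atom class pair.

    Owner atoms are classified as sn-1 chain carbon, sn-2 chain carbon,
    or other lipid atom; keys are ``"sn1-sn1"``, ``"sn1-sn2"``,
    ``"sn2-sn1"``, ``"sn2-sn2"`` (top-bottom order) and ``"other"``
    (any face with a non-chain owner).  Fractions sum to 1.
    """
    if len(mesh) == 0:
        raise ValueError("empty interface mesh")
    cls = chains.atom_chain_class(n_atoms)
    ct = cls[mesh.atom_top]
    cb = cls[mesh.atom_bottom]
    total = mesh.total_area
    out = {}
    for t in ("sn1", "sn2"):
        for b in ("sn1", "sn2"):
            sel = (ct == t) & (cb == b)
            out[f"{t}-{b}"] = float(mesh.areas[sel].sum() / total)
    out["other"] = float(mesh.areas[(ct == "other") | (cb == "other")].sum() / total)
    return out


def intensity_map(mesh: InterfaceMesh, resolution: float = 1.0):
    """2D map of interface depth |z| on a regular xy grid.

    Each face deposits its vertex-mean |z| at its centroid's grid cell
    (area-weighted when several faces land in one cell); cells not hit
    by any face centroid are filled from the nearest face centroid.
    Darker (larger) values mark deeper interdigitation.

    Returns ``(values, (x_edges, y_edges))`` with ``values`` of shape
    (nx, ny).
    """
    if resolution <= 0:
        raise ValueError("grid resolution must be positive")
    if len(mesh) == 0:
        raise ValueError("empty interface mesh")
    lx, ly = mesh.box[0], mesh.box[1]
    nx = max(1, int(np.ceil(lx / resolution)))
    ny = max(1, int(np.ceil(ly / resolution)))
    centroids = np.array([v.mean(axis=0) for v in mesh.vertices])
    cxy = np.mod(centroids[:, :2], [lx, ly])
    depth = np.array([np.abs(v[:, 2]).mean() for v in mesh.vertices])
    ix = np.minimum((cxy[:, 0] / lx * nx).astype(int), nx - 1)
    iy = np.minimum((cxy[:, 1] / ly * ny).astype(int), ny - 1)
    wsum = np.zeros((nx, ny))
    dsum = np.zeros((nx, ny))
    np.add.at(wsum, (ix, iy), mesh.areas)
    np.add.at(dsum, (ix, iy), mesh.areas * depth)
    values = np.full((nx, ny), np.nan)
    hit = wsum > 0
    values[hit] = dsum[hit] / wsum[hit]
    if not hit.all():
        # nearest-face fill for cells finer than the face spacing
        tree = cKDTree(cxy)
        gx = (np.arange(nx) + 0.5) * lx / nx
        gy = (np.arange(ny) + 0.5) * ly / ny
        mx, my = np.meshgrid(gx, gy, indexing="ij")
        empty = ~hit
        _, nearest = tree.query(np.column_stack([mx[empty], my[empty]]))
        values[empty] = depth[nearest]
    x_edges = np.linspace(0, lx, nx + 1)
    y_edges = np.linspace(0, ly, ny + 1)
    return values, (x_edges, y_edges)


def export_mesh(mesh: InterfaceMesh, path):
    """Write the interface as a Wavefront OBJ (centroid-fan triangles)."""
    with open(path, "w") as fh:
        fh.write("# interleaflet interface mesh\n")
        nv = 0
        tri = []
        for verts in mesh.vertices:
            c = verts.mean(axis=0)
            rel = verts - c
            _, _, vt = np.linalg.svd(rel, full_matrices=False)
            ang = np.arctan2(rel @ vt[1], rel @ vt[0])
            ordered = verts[np.argsort(ang)]
            for v in ordered:
                fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            fh.write(f"v {c[0]:.6f} {c[1]:.6f} {c[2]:.6f}\n")
            k = len(ordered)
            centroid_id = nv + k + 1
            for t in range(k):
                tri.append((nv + t + 1, nv + (t + 1) % k + 1, centroid_id))
            nv += k + 1
        for a, b, c in tri:
            fh.write(f"f {a} {b} {c}\n")


def load_obj(path):
    """Read an OBJ written by :func:`export_mesh`.

    Returns ``(vertices, triangles)`` with 0-based triangle indices;
    intended for round-trip audits of exported meshes.
    """
    verts, tris = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                tris.append([int(x.split("/")[0]) - 1 for x in parts[1:4]])
    return np.asarray(verts), np.asarray(tris, dtype=int)


def mesh_obj_area(path) -> float:
    """Total triangle area of an exported OBJ mesh."""
    verts, tris = load_obj(path)
    a = verts[tris[:, 0]]
    b = verts[tris[:, 1]]
    c = verts[tris[:, 2]]
    return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())
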