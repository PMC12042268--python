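"""Synthetic bilayer-like configurations with controllable interdigitation.

These fixtures are statistical stand-ins, not physical membranes: each
"lipid" is a headgroup anchor (P) plus two acyl-chain columns of carbons
whose z coordinates follow per-carbon Gaussian distributions that
approach the midplane toward the chain terminus.  The penetration depth
``delta`` sets how far the terminal carbon's mean z extends past the
midplane into the opposing leaflet, which lets every interdigitation
metric be exercised on configurations with a known answer.  Water-like
generator points cap the system above and below so the 3D Voronoi
tessellation has bounded, physically sensible cells at the z extremes.

Atom naming follows the CHARMM convention (sn-1: C32..., sn-2: C22...,
anchor P) so fixtures exercise the same I/O and chain-indexing path as
real trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import Frame, Topology

_MASS = {"P": 30.974, "C": 12.011, "O": 15.9994}


@dataclass
class FixtureSpec:
    """Parameters of a synthetic bilayer fixture.

    Attributes
    ----------
    lipids_per_leaflet : int
        Number of lipid columns per leaflet (a perfect square for the
        flat lattice).
    n_sn1, n_sn2 : int
        Chain carbons per sn-1 / sn-2 chain.
    box : (Lx, Ly, Lz), Angstrom
    head_depth : float, Angstrom
        Mean |z| of the first (glycerol-proximal) chain carbon.
    sigma : float, Angstrom
        Gaussian z-spread of each chain carbon.
    delta : float, Angstrom
        Penetration depth: how far the terminal carbon's mean z extends
        past the midplane into the opposing leaflet (0 = terminus at the
        midplane on average).
    gap : float, Angstrom
        Half-gap parameter of the flat lattice (terminal methyls sit at
        z = +-gap/2; no atom crosses the midplane).
    carbon_spacing : float, Angstrom
        Vertical spacing between successive carbons in the flat lattice.
    waters_per_lipid : int
        Water-like generator points per lipid (Gaussian fixture).
    n_frames : int
    seed : int
        Fixed seed => bit-reproducible output.
    depth_profile : array or None
        Optional explicit per-carbon mean-depth profile (overrides the
        linear head_depth -> -delta default; length max(n_sn1, n_sn2)).
    """

    lipids_per_leaflet: int = 16
    n_sn1: int = 4
    n_sn2: int = 4
    box: tuple = (32.0, 32.0, 60.0)
    head_depth: float = 12.0
    sigma: float = 2.0
    delta: float = 0.0
    gap: float = 3.0
    carbon_spacing: float = 2.5
    waters_per_lipid: int = 4
    n_frames: int = 1
    seed: int = 0
    depth_profile: np.ndarray | None = None

    def __post_init__(self):
        if self.lipids_per_leaflet < 1 or self.n_sn1 < 1 or self.n_sn2 < 1:
            raise ValueError("lipid and chain counts must be positive")
        if any(b <= 0 for b in self.box):
            raise ValueError("box lengths must be positive")
        if self.sigma < 0 or self.n_frames < 1:
            raise ValueError("sigma must be >= 0 and n_frames >= 1")

    def chain_means(self, n_carbons: int) -> np.ndarray:
        """Mean z (top leaflet) per carbon, glycerol-proximal to terminal."""
        if self.depth_profile is not None:
            prof = np.asarray(self.depth_profile, dtype=float)
            return prof[:n_carbons]
        return np.linspace(self.head_depth, -self.delta, n_carbons)


def _lipid_atom_names(n_sn1: int, n_sn2: int):
    names = ["P"]
    names += [f"C3{k}" for k in range(2, n_sn1 + 2)]
    names += [f"C2{k}" for k in range(2, n_sn2 + 2)]
    return names


def _build_topology(n_lipids: int, n_sn1: int, n_sn2: int, n_waters: int) -> Topology:
    names, types, masses, charges, resids, resnames = [], [], [], [], [], []
    lipid_names = _lipid_atom_names(n_sn1, n_sn2)
    resid = 0
    for _ in range(n_lipids):
        resid += 1
        for nm in lipid_names:
            names.append(nm)
            types.append("PL" if nm == "P" else "CTL2")
            masses.append(_MASS["P"] if nm == "P" else _MASS["C"])
            charges.append(0.0)
            resids.append(resid)
            resnames.append("LIP")
    for _ in range(n_waters):
        resid += 1
        names.append("OH2")
        types.append("OT")
        masses.append(_MASS["O"])
        charges.append(0.0)
        resids.append(resid)
        resnames.append("TIP3")
    return Topology(names=names, types=types, masses=masses, charges=charges,
                    resids=resids, resnames=resnames)


def _water_lattice_layers(spec: FixtureSpec, z_top: float, n_layers: int = 3,
                          spacing: float = 3.0):
    """Water-like generator points as lattice layers beyond |z_top|."""
    lx, ly, lz = spec.box
    n_target = max(spec.lipids_per_leaflet * spec.waters_per_lipid, 4)
    m = max(2, math.ceil(math.sqrt(n_target / n_layers)))
    xs = (np.arange(m) + 0.5) * lx / m
    ys = (np.arange(m) + 0.5) * ly / m
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = []
    for side in (+1, -1):
        for layer in range(n_layers):
            z = side * (z_top + (layer + 1) * spacing)
            if abs(z) >= lz / 2:
                z = side * (lz / 2 - 0.5 - 0.1 * layer)
            layer_pts = np.column_stack(
                [gx.ravel(), gy.ravel(), np.full(gx.size, z)])
            pts.append(layer_pts)
    return np.concatenate(pts)


def make_flat_lattice(spec: FixtureSpec):
    """Regular-lattice fixture: two slabs meeting at z = 0 with a uniform gap.

    The flat interface is the analytic reference: the cross-leaflet
    Voronoi interface is a plane of area Lx*Ly, so nISA = 1.  Requires
    ``delta == 0`` and ``sigma == 0`` and a perfect-square lipid count
    (otherwise the lattice is not commensurate with the box).
    """
    if spec.delta != 0 or spec.sigma != 0:
        raise ValueError("flat lattice requires delta = 0 and sigma = 0")
    n = spec.lipids_per_leaflet
    m = math.isqrt(n)
    if m * m != n:
        raise ValueError(
            f"lattice spacing incompatible with box: {n} lipids per leaflet "
            "is not a perfect square")
    lx, ly, lz = spec.box
    sx, sy = lx / m, ly / m
    chain_dx = min(sx, sy) / 4.0  # lateral offset so the two chains never coincide

    coords = []
    for side in (+1, -1):
        for i in range(m):
            for j in range(m):
                x0 = (i + 0.5) * sx
                y0 = (j + 0.5) * sy
                # carbons run glycerol-proximal (far from midplane) -> terminal
                z_term = side * spec.gap / 2.0
                p_z = z_term + side * (max(spec.n_sn1, spec.n_sn2)
                                       * spec.carbon_spacing + 2.0)
                lipid = [[x0, y0, p_z]]
                for n_c, dx in ((spec.n_sn1, -chain_dx), (spec.n_sn2, +chain_dx)):
                    zs = z_term + side * spec.carbon_spacing * np.arange(n_c)[::-1]
                    for z in zs:
                        lipid.append([x0 + dx, y0, z])
                coords.extend(lipid)
    coords = np.asarray(coords, dtype=float)
    z_head = float(np.max(np.abs(coords[:, 2])))
    waters = _water_lattice_layers(spec, z_head, n_layers=2)
    all_coords = np.concatenate([coords, waters])
    top = _build_topology(2 * n, spec.n_sn1, spec.n_sn2, len(waters))
    frame = Frame(coords=all_coords, box=np.asarray(spec.box), time=0.0)
    frames = [Frame(coords=all_coords.copy(), box=np.asarray(spec.box), time=float(k))
              for k in range(spec.n_frames)]
    del frame
    return top, frames


def make_gaussian_bilayer(spec: FixtureSpec):
    """Fixture with per-carbon Gaussian z-distributions.

    Each chain carbon's z is drawn from N(mean_k, sigma) where the means
    run linearly from ``head_depth`` to ``-delta`` along the chain; the
    sampled carbons are re-sorted per chain so depth order is preserved.
    The bottom leaflet mirrors the top about z = 0 (independent draws).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.lipids_per_leaflet
    lx, ly, lz = spec.box
    frames = []
    n_atoms_per_lipid = 1 + spec.n_sn1 + spec.n_sn2
    means_sn1 = spec.chain_means(spec.n_sn1)
    means_sn2 = spec.chain_means(spec.n_sn2)
    z_head = spec.head_depth + 3.0
    waters_template = _water_lattice_layers(spec, z_head + 1.0)
    for k in range(spec.n_frames):
        coords = np.empty((2 * n * n_atoms_per_lipid, 3))
        a = 0
        for side in (+1, -1):
            xy = rng.uniform([0, 0], [lx, ly], size=(n, 2))
            for li in range(n):
                coords[a] = [xy[li, 0], xy[li, 1],
                             side * (z_head + rng.normal(0.0, spec.sigma))]
                a += 1
                for means in (means_sn1, means_sn2):
                    z = side * (means + rng.normal(0.0, spec.sigma, size=len(means)))
                    # keep carbons in depth order along the chain
                    z = side * np.sort(side * z)[::-1]
                    cxy = xy[li] + rng.normal(0.0, 1.0, size=(len(means), 2))
                    coords[a:a + len(means), :2] = cxy
                    coords[a:a + len(means), 2] = z
                    a += len(means)
        all_coords = np.concatenate([coords, waters_template])
        frames.append(Frame(coords=all_coords, box=np.asarray(spec.box),
                            time=float(k)))
    top = _build_topology(2 * n, spec.n_sn1, spec.n_sn2, len(waters_template))
    return top, frames


# ---------------------------------------------------------------------------
# fixture output: PSF + DCD (the formats the readers consume) + text dump

def write_psf(topology: Topology, path):
    """Write a minimal X-PLOR-style PSF (atoms only, no bonds)."""
    lines = ["PSF", "", "       1 !NTITLE", " REMARKS synthetic bilayer fixture", ""]
    lines.append(f"{topology.n_atoms:8d} !NATOM")
    for i in range(topology.n_atoms):
        lines.append(
            f"{i + 1:8d} MEMB {topology.resids[i]:<6d} "
            f"{str(topology.resnames[i]):<6s} {str(topology.names[i]):<6s} "
            f"{str(topology.types[i]):<6s} {topology.charges[i]:12.6f}  "
            f"{topology.masses[i]:12.6f} {0:11d}"
        )
    lines += ["", "       0 !NBOND: bonds", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def write_dcd(frames, path):
    """Write frames as a DCD coordinate trajectory."""
    import MDAnalysis as mda

    n_atoms = frames[0].coords.shape[0]
    u = mda.Universe.empty(n_atoms, trajectory=True)
    with mda.Writer(str(path), n_atoms) as w:
        for f in frames:
            u.atoms.positions = f.coords
            u.dimensions = [f.box[0], f.box[1], f.box[2], 90.0, 90.0, 90.0]
            w.write(u.atoms)


def write_fixture(topology: Topology, frames, psf_path, dcd_path, txt_path=None):
    """Write a fixture as PSF + DCD (and optionally a plain-text dump)."""
    write_psf(topology, psf_path)
    write_dcd(frames, dcd_path)
    if txt_path is not None:
        with open(txt_path, "w") as fh:
            for k, f in enumerate(frames):
                fh.write(f"# frame {k} box {f.box[0]:.4f} {f.box[1]:.4f} "
                         f"{f.box[2]:.4f}\n")
                for i, (x, y, z) in enumerate(f.coords):
                    fh.write(f"{i + 1} {topology.names[i]} {x:.6f} {y:.6f} {z:.6f}\n")
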