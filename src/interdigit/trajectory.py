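"""Reading PSF/DCD trajectories and preparing frames for analysis.

All analyses assume frames centered so that the mass-weighted center of
the lipid terminal-methyl carbons sits at z = 0, with the top leaflet
defined as the one whose headgroup anchor (phosphorus by default) has
trajectory-averaged z > 0.  This module reads topologies and coordinate
trajectories through MDAnalysis, enumerates acyl-chain carbons from
CHARMM atom names (sn-1: C32, C33, ...; sn-2: C22, C23, ...), repairs
molecules split by periodic imaging, centers frames, and assigns
leaflets.
"""

from __future__ import annotations

import re
import warnings

import numpy as np

from .core import (
    BOTTOM,
    DEFAULT_LIPID_RESNAMES,
    DEFAULT_WATER_RESNAMES,
    TOP,
    ChainIndexing,
    Frame,
    LeafletMap,
    Topology,
    TopologyError,
    minimum_image,
)

_SN1_PATTERN = re.compile(r"^C3(\d+)$")
_SN2_PATTERN = re.compile(r"^C2(\d+)$")


def load_topology(path, lipid_resnames=DEFAULT_LIPID_RESNAMES,
                  water_resnames=DEFAULT_WATER_RESNAMES) -> Topology:
    """Read a PSF (CHARMM/X-PLOR) topology file.

    Raises :class:`TopologyError` if no lipid residues are found under
    the configured residue-name lists.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # no-coordinate universe
        u = mda.Universe(str(path))
    top = Topology(
        names=u.atoms.names.astype(object),
        types=u.atoms.types.astype(object),
        masses=u.atoms.masses,
        charges=u.atoms.charges,
        resids=u.atoms.resids,
        resnames=u.atoms.resnames.astype(object),
        lipid_resnames=tuple(lipid_resnames),
        water_resnames=tuple(water_resnames),
    )
    if top.n_lipids == 0:
        raise TopologyError(f"zero lipid residues found in {path}")
    return top


def load_trajectory(psf_path, traj_path, start=None, stop=None, stride=None,
                    lipid_resnames=DEFAULT_LIPID_RESNAMES,
                    water_resnames=DEFAULT_WATER_RESNAMES):
    """Read topology + trajectory; returns ``(Topology, list[Frame])``.

    Box lengths are taken from each frame's unit cell (orthorhombic
    required); times are converted from ps to ns.
    """
    import MDAnalysis as mda

    top = load_topology(psf_path, lipid_resnames, water_resnames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(psf_path), str(traj_path))
    frames = []
    for ts in u.trajectory[slice(start, stop, stride)]:
        dims = ts.dimensions
        if dims is None or np.any(np.asarray(dims[:3]) <= 0):
            raise ValueError(f"frame {ts.frame} has no valid box dimensions")
        if not np.allclose(dims[3:6], 90.0, atol=1e-3):
            raise ValueError("only orthorhombic boxes are supported")
        frames.append(Frame(coords=ts.positions.astype(float).copy(),
                            box=np.asarray(dims[:3], dtype=float),
                            time=float(ts.time) / 1000.0))
    return top, frames


def index_chains(topology: Topology, sn1_pattern=_SN1_PATTERN,
                 sn2_pattern=_SN2_PATTERN) -> ChainIndexing:
    """Enumerate sn-1 and sn-2 chain carbons for every lipid residue.

    Chain carbons are identified by CHARMM names (C3n for sn-1, C2n for
    sn-2, n >= 2; the ester carbonyl carbons C21/C31 are not chain
    carbons and are excluded).  Lists are ordered toward the terminal
    methyl and must be contiguous in n.
    """
    chains = ChainIndexing()
    for resid in topology.lipid_resids:
        atom_idx = topology.atoms_of_residue(resid)
        for pattern, store in ((sn1_pattern, chains.sn1), (sn2_pattern, chains.sn2)):
            found = {}
            for i in atom_idx:
                m = pattern.match(str(topology.names[i]))
                if m:
                    n = int(m.group(1))
                    if n >= 2:
                        found[n] = i
            if not found:
                raise TopologyError(f"lipid residue {resid}: no chain carbons match")
            ns = sorted(found)
            if ns != list(range(ns[0], ns[-1] + 1)):
                raise TopologyError(
                    f"lipid residue {resid}: chain carbons are not contiguous ({ns})"
                )
            store[resid] = np.asarray([found[n] for n in ns], dtype=int)
    return chains


def unwrap_molecules(frame: Frame, topology: Topology) -> Frame:
    """Rejoin molecules split across periodic boundaries.

    Each residue's atoms are moved to the periodic image closest to the
    residue's first atom (minimum-image displacement), so intramolecular
    geometry is contiguous before centering/analysis.
    """
    coords = frame.coords.copy()
    box = frame.box
    # residues are contiguous blocks in well-formed PSFs; handle general case
    order = np.argsort(topology.resids, kind="stable")
    resids_sorted = topology.resids[order]
    boundaries = np.flatnonzero(np.diff(resids_sorted)) + 1
    for block in np.split(order, boundaries):
        ref = coords[block[0]]
        disp = coords[block] - ref
        coords[block] = ref + minimum_image(disp, box)
    return Frame(coords=coords, box=box, time=frame.time)


def center_frame(frame: Frame, topology: Topology,
                 chains: ChainIndexing | None = None) -> Frame:
    """Translate so the terminal-methyl mass-weighted COM has z = 0.

    Only the methyl carbons enter the COM (their hydrogens contribute
    little mass and shift the reference by < 0.05 A); x and y are left
    unchanged.  The operation is a rigid translation and is idempotent.
    """
    if chains is None:
        chains = index_chains(topology)
    idx = chains.terminal_methyl_indices()
    m = topology.masses[idx]
    z_com = float(np.average(frame.coords[idx, 2], weights=m))
    if abs(z_com) < 1e-9:  # already centered; keep the op idempotent
        return Frame(coords=frame.coords.copy(), box=frame.box,
                     time=frame.time)
    shifted = frame.coords.copy()
    shifted[:, 2] -= z_com
    return Frame(coords=shifted, box=frame.box, time=frame.time)


def assign_leaflets(topology: Topology, frames, anchor_name: str = "P",
                    tol: float = 1.0) -> LeafletMap:
    """Label each lipid top/bottom from its anchor atom's mean z.

    A lipid is *top* iff its anchor atom (headgroup phosphorus by
    default) has trajectory-averaged z > 0 over the supplied centered
    frames.  Lipids whose mean anchor z lies within ``tol`` Angstrom of
    the midplane trigger a warning but are still assigned by sign.
    """
    if isinstance(frames, Frame):
        frames = [frames]
    frames = list(frames)
    if not frames:
        raise ValueError("at least one frame is required")
    labels = {}
    for resid in topology.lipid_resids:
        atom_idx = topology.atoms_of_residue(resid)
        names = topology.names[atom_idx]
        anchor = atom_idx[np.asarray([str(n) == anchor_name for n in names])]
        if len(anchor) != 1:
            raise TopologyError(
                f"lipid residue {resid}: expected exactly one anchor atom "
                f"'{anchor_name}', found {len(anchor)}"
            )
        z_mean = float(np.mean([f.coords[anchor[0], 2] for f in frames]))
        if abs(z_mean) < tol:
            warnings.warn(
                f"lipid residue {resid}: anchor mean z = {z_mean:.2f} A is close "
                "to the midplane; assigned by sign", stacklevel=2)
        labels[resid] = TOP if z_mean > 0 else BOTTOM
    lm = LeafletMap(labels)
    if len(lm.top_resids) == 0 or len(lm.bottom_resids) == 0:
        raise TopologyError("one leaflet is empty after assignment")
    return lm


def check_leaflet_stability(topology: Topology, frames, leaflets: LeafletMap,
                            anchor_name: str = "P") -> bool:
    """Warn if any lipid's anchor changes sign on any frame (flip-flop).

    Returns True when the map is stable over all frames.
    """
    stable = True
    for resid, side in leaflets.labels.items():
        atom_idx = topology.atoms_of_residue(resid)
        names = topology.names[atom_idx]
        anchor = atom_idx[np.asarray([str(n) == anchor_name for n in names])][0]
        z = np.asarray([f.coords[anchor, 2] for f in frames])
        if np.any(np.sign(z) != side):
            warnings.warn(f"lipid residue {resid}: anchor crosses the midplane "
                          "during the trajectory", stacklevel=2)
            stable = False
    return stable


def prepare_frames(topology: Topology, frames, chains: ChainIndexing | None = None,
                   unwrap: bool = True):
    """Unwrap (optional) and center every frame; returns the new list."""
    if chains is None:
        chains = index_chains(topology)
    out = []
    for f in frames:
        if unwrap:
            f = unwrap_molecules(f, topology)
        out.append(center_frame(f, topology, chains))
    return out
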