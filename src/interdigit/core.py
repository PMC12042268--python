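"""Core in-memory containers for bilayer trajectory analysis.

A :class:`Topology` is a flat, array-backed atom table (names, masses,
residue membership) with lipid/water residues classified by residue name.
A :class:`Frame` is one set of coordinates plus an orthorhombic periodic
box.  :class:`ChainIndexing` maps each lipid residue to its ordered sn-1
and sn-2 acyl-chain carbons, and :class:`LeafletMap` assigns every lipid
residue to the top or bottom leaflet.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Residue names recognised as lipids by default (common PCs plus the
#: synthetic fixture residue name).
DEFAULT_LIPID_RESNAMES = (
    "DPPC", "MSPC", "DMPC", "DSPC", "DOPC", "POPC", "DLPC", "PSPC", "LIP",
)

#: Residue names recognised as water by default.
DEFAULT_WATER_RESNAMES = ("TIP3", "TIP3P", "TIP4", "SPC", "SPCE", "WAT", "HOH", "SOL")

TOP = 1
BOTTOM = -1


class TopologyError(ValueError):
    """Raised when a topology cannot be interpreted as a bilayer system."""


@dataclass
class Topology:
    """Atom table for one system.

    Parameters
    ----------
    names, types : arrays of str, shape (n_atoms,)
        Atom names (CHARMM convention, e.g. ``C216``) and force-field types.
    masses : array, amu
    charges : array, elementary charge
    resids : int array
        Residue id per atom.
    resnames : array of str
        Residue name per atom.
    lipid_resnames, water_resnames : tuple of str
        Residue-name whitelists used to classify residues.
    """

    names: np.ndarray
    types: np.ndarray
    masses: np.ndarray
    charges: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    lipid_resnames: tuple = DEFAULT_LIPID_RESNAMES
    water_resnames: tuple = DEFAULT_WATER_RESNAMES

    def __post_init__(self):
        self.names = np.asarray(self.names, dtype=object)
        self.types = np.asarray(self.types, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        n = len(self.names)
        for arr in (self.types, self.masses, self.charges, self.resids, self.resnames):
            if len(arr) != n:
                raise TopologyError("per-atom arrays have inconsistent lengths")
        if np.any(self.masses <= 0):
            raise TopologyError("all atomic masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def _residue_table(self):
        # first-occurrence order of residues
        _, first = np.unique(self.resids, return_index=True)
        order = np.sort(first)
        return self.resids[order], self.resnames[order]

    @property
    def lipid_resids(self) -> np.ndarray:
        rid, rname = self._residue_table()
        mask = np.isin(rname.astype(str), self.lipid_resnames)
        return rid[mask]

    @property
    def water_resids(self) -> np.ndarray:
        rid, rname = self._residue_table()
        mask = np.isin(rname.astype(str), self.water_resnames)
        return rid[mask]

    @property
    def n_lipids(self) -> int:
        return len(self.lipid_resids)

    @property
    def n_waters(self) -> int:
        return len(self.water_resids)

    def is_lipid_atom(self) -> np.ndarray:
        """Boolean mask of atoms belonging to lipid residues."""
        return np.isin(self.resids, self.lipid_resids)

    def is_water_atom(self) -> np.ndarray:
        return np.isin(self.resids, self.water_resids)

    def atoms_of_residue(self, resid: int) -> np.ndarray:
        return np.flatnonzero(self.resids == resid)


@dataclass
class Frame:
    """One trajectory frame: coordinates (Angstrom) and orthorhombic box."""

    coords: np.ndarray  # (n_atoms, 3), Angstrom
    box: np.ndarray     # (Lx, Ly, Lz), Angstrom
    time: float = 0.0   # ns

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths (Lx, Ly, Lz)")

    @property
    def axy(self) -> float:
        """Lateral (xy) box area in Angstrom^2."""
        return float(self.box[0] * self.box[1])

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def translated(self, shift) -> "Frame":
        """Rigidly translated copy."""
        return replace(self, coords=self.coords + np.asarray(shift, dtype=float))


@dataclass
class ChainIndexing:
    """Ordered sn-1 / sn-2 carbon atom indices per lipid residue.

    ``sn1[resid]`` and ``sn2[resid]`` are arrays of atom indices ordered
    from the glycerol-proximal carbon (C32 / C22 in CHARMM naming) to the
    terminal methyl.
    """

    sn1: dict = field(default_factory=dict)
    sn2: dict = field(default_factory=dict)

    @property
    def resids(self):
        return list(self.sn1)

    def chain_lengths(self):
        """(len sn-1, len sn-2); requires all lipids to share one length."""
        l1 = {len(v) for v in self.sn1.values()}
        l2 = {len(v) for v in self.sn2.values()}
        if len(l1) != 1 or len(l2) != 1:
            raise TopologyError(
                "mixed acyl chain lengths; per-species analysis is required"
            )
        return l1.pop(), l2.pop()

    def terminal_methyl_indices(self) -> np.ndarray:
        """Atom indices of all terminal-methyl carbons (both chains)."""
        idx = [chain[-1] for chain in self.sn1.values()]
        idx += [chain[-1] for chain in self.sn2.values()]
        return np.asarray(sorted(idx), dtype=int)

    def atom_chain_class(self, n_atoms: int) -> np.ndarray:
        """Per-atom label: 'sn1', 'sn2' or 'other'."""
        cls = np.full(n_atoms, "other", dtype=object)
        for chain in self.sn1.values():
            cls[chain] = "sn1"
        for chain in self.sn2.values():
            cls[chain] = "sn2"
        return cls


@dataclass
class LeafletMap:
    """Leaflet label (+1 top / -1 bottom) per lipid residue."""

    labels: dict  # resid -> TOP or BOTTOM

    @property
    def top_resids(self) -> np.ndarray:
        return np.asarray(sorted(r for r, s in self.labels.items() if s == TOP))

    @property
    def bottom_resids(self) -> np.ndarray:
        return np.asarray(sorted(r for r, s in self.labels.items() if s == BOTTOM))

    def swapped(self) -> "LeafletMap":
        return LeafletMap({r: -s for r, s in self.labels.items()})

    def atom_labels(self, topology: Topology) -> np.ndarray:
        """Per-atom leaflet label: +1 top, -1 bottom, 0 for non-lipid atoms."""
        out = np.zeros(topology.n_atoms, dtype=np.int8)
        for resid, side in self.labels.items():
            out[topology.resids == resid] = side
        return out


def wrap_coords(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary image [0, L) in each dimension."""
    return np.mod(coords, box)


def minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors for an orthorhombic box."""
    return disp - box * np.round(disp / box)
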