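"""High-level handle tying topology, frames, chain indexing and leaflets.

``Bilayer`` is the convenience entry point for interactive use::

    from interdigit import Bilayer
    bl = Bilayer.from_files("system.psf", "traj.dcd", stride=10)
    table = bl.nisa_series()          # per-frame nISA
    ccmat, totals = bl.ccmat()        # contact matrix + per-frame totals
    dom = bl.domat()                  # density-overlap matrix
    value, variants = bl.memit()      # leaflet mass-density overlap

Frames are unwrap-repaired and centered on construction (terminal-methyl
COM at z = 0) and leaflets assigned from the trajectory-averaged anchor
z, so every metric sees the conventions it assumes.
"""

from __future__ import annotations

import numpy as np

from . import contacts, density, trajectory, voronoi
from .core import ChainIndexing, LeafletMap, Topology
from .synth import FixtureSpec, make_flat_lattice, make_gaussian_bilayer


class Bilayer:
    """A prepared bilayer trajectory ready for interdigitation analysis."""

    def __init__(self, topology: Topology, frames, chains: ChainIndexing = None,
                 leaflets: LeafletMap = None, anchor_name: str = "P",
                 prepare: bool = True):
        self.topology = topology
        self.chains = chains or trajectory.index_chains(topology)
        if prepare:
            frames = trajectory.prepare_frames(topology, frames, self.chains)
        self.frames = list(frames)
        self.leaflets = leaflets or trajectory.assign_leaflets(
            topology, self.frames, anchor_name=anchor_name)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_files(cls, psf_path, traj_path, start=None, stop=None, stride=None,
                   **kwargs) -> "Bilayer":
        top, frames = trajectory.load_trajectory(psf_path, traj_path,
                                                 start, stop, stride)
        return cls(top, frames, **kwargs)

    @classmethod
    def from_spec(cls, spec: FixtureSpec, kind: str = "gaussian", **kwargs
                  ) -> "Bilayer":
        """Build from the synthetic fixture generator (flat or gaussian)."""
        maker = {"flat": make_flat_lattice, "gaussian": make_gaussian_bilayer}
        top, frames = maker[kind](spec)
        return cls(top, frames, **kwargs)

    # -- metrics ------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def nisa_series(self, jitter: float = 1e-6):
        return voronoi.nisa_series(self.frames, self.topology, self.leaflets,
                                   jitter=jitter)

    def interface_mesh(self, frame_index: int = 0):
        diagram = voronoi.tessellate(self.frames[frame_index], self.topology)
        return voronoi.interface_mesh(diagram, self.leaflets, self.topology)

    def ccmat(self, cutoff: float = contacts.DEFAULT_CUTOFF):
        return contacts.average_ccmat(self.frames, self.topology, self.chains,
                                      self.leaflets, cutoff)

    def domat(self, bin_width: float = density.DEFAULT_BIN_WIDTH):
        return density.domat(self.frames, self.topology, self.chains,
                             self.leaflets, bin_width)

    def memit(self, bin_width: float = density.DEFAULT_BIN_WIDTH,
              variant: str = "membplugin"):
        return density.memit(self.frames, self.topology, self.leaflets,
                             bin_width, variant)

    def area_per_lipid(self) -> np.ndarray:
        """Per-frame lateral area per lipid (A_xy / lipids per leaflet)."""
        n_per_leaflet = len(self.leaflets.top_resids)
        return np.array([f.axy / n_per_leaflet for f in self.frames])
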