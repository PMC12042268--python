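"""Number-density profiles along z, overlap matrices (doMat) and memIT.

The number-density profile (NDP) of an atom selection is the histogram
of z coordinates, normalized per frame by (bin width x that frame's
lateral area A_xy) and averaged over frames, giving atoms per A^3.
Because the box z extent fluctuates, profiles are accumulated on a fixed
global grid spanning the largest box.

The overlap of two profiles is

    Omega = integral over z of min(rho_1(z), rho_2(z)) dz    [A^-2]

computed by the rectangle rule on the common grid (consistent with the
histogram estimator).  doMat collects Omega_ij for every pair of
(top-leaflet carbon position i, bottom-leaflet carbon position j),
each position's profile aggregating the equivalent carbon over all
lipids of its leaflet.  memIT is the analogous scalar overlap of the
whole-leaflet mass-density profiles; two standard variants are
provided (see :func:`memit`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import CarbonMatrix, _position_labels, carbon_position_table
from .core import ChainIndexing, Frame, LeafletMap, Topology

DEFAULT_BIN_WIDTH = 1.0  # Angstrom


@dataclass
class DensityProfile:
    """z-resolved density (number or mass per A^3), frame-averaged."""

    z_centers: np.ndarray
    values: np.ndarray
    bin_width: float
    label: str = ""
    n_frames: int = 0

    def __post_init__(self):
        self.z_centers = np.asarray(self.z_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.z_centers.shape != self.values.shape:
            raise ValueError("z grid and values must have the same shape")
        if np.any(self.values < 0):
            raise ValueError("densities must be non-negative")

    @property
    def integral(self) -> float:
        """integral of rho dz (per A^2), rectangle rule."""
        return float(self.values.sum() * self.bin_width)


def _global_z_edges(frames, bin_width: float):
    zmax = max(f.box[2] for f in frames) / 2.0
    nbins = int(np.ceil(2 * zmax / bin_width))
    return -zmax + bin_width * np.arange(nbins + 1)


def density_profile(frames, atom_indices, bin_width: float = DEFAULT_BIN_WIDTH,
                    weights: np.ndarray | None = None, label: str = "",
                    z_edges: np.ndarray | None = None) -> DensityProfile:
    """Frame-averaged density profile of an atom selection.

    ``weights`` (e.g. atomic masses, amu) turns the number density into
    a mass density.  Normalization per frame uses that frame's A_xy, so
    the closure integral rho dz * mean A_xy recovers the selection size
    (or total mass).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    atom_indices = np.asarray(atom_indices, dtype=int)
    if atom_indices.size == 0:
        raise ValueError("empty atom selection")
    frames = list(frames)
    if z_edges is None:
        z_edges = _global_z_edges(frames, bin_width)
    acc = np.zeros(len(z_edges) - 1)
    w = None if weights is None else np.asarray(weights, dtype=float)
    for f in frames:
        hist, _ = np.histogram(f.coords[atom_indices, 2], bins=z_edges, weights=w)
        acc += hist / (bin_width * f.axy)
    centers = 0.5 * (z_edges[:-1] + z_edges[1:])
    return DensityProfile(z_centers=centers, values=acc / len(frames),
                          bin_width=bin_width, label=label, n_frames=len(frames))


def overlap_integral(p1: DensityProfile, p2: DensityProfile) -> float:
    """Overlap area Omega = integral min(rho_1, rho_2) dz, in A^-2.

    Symmetric in its arguments and bounded above by the smaller of the
    two profile integrals.  Requires identical binning.
    """
    if (p1.bin_width != p2.bin_width
            or p1.z_centers.shape != p2.z_centers.shape
            or not np.allclose(p1.z_centers, p2.z_centers)):
        raise ValueError("profiles must share an identical z grid")
    return float(np.minimum(p1.values, p2.values).sum() * p1.bin_width)


class ProfileAccumulator:
    """Additive histogram accumulator for block-parallel profile averaging.

    Holds one running (per-frame A_xy normalized) histogram per profile
    on a shared global z grid; accumulators from disjoint frame blocks
    merge by plain addition, so block-parallel results are bitwise
    identical to a single pass.
    """

    def __init__(self, z_edges: np.ndarray, selections, weights=None,
                 labels=None):
        self.z_edges = np.asarray(z_edges, dtype=float)
        self.bin_width = float(self.z_edges[1] - self.z_edges[0])
        self.selections = [np.asarray(s, dtype=int) for s in selections]
        self.weights = weights if weights is not None else [None] * len(selections)
        self.labels = labels if labels is not None else [""] * len(selections)
        self.acc = np.zeros((len(selections), len(self.z_edges) - 1))
        self.n_frames = 0

    def add_frame(self, frame: Frame):
        norm = self.bin_width * frame.axy
        for i, sel in enumerate(self.selections):
            hist, _ = np.histogram(frame.coords[sel, 2], bins=self.z_edges,
                                   weights=self.weights[i])
            self.acc[i] += hist / norm
        self.n_frames += 1

    def merge(self, other: "ProfileAccumulator"):
        if not np.array_equal(self.z_edges, other.z_edges):
            raise ValueError("accumulators must share a z grid")
        self.acc += other.acc
        self.n_frames += other.n_frames

    def profile(self, i: int) -> DensityProfile:
        centers = 0.5 * (self.z_edges[:-1] + self.z_edges[1:])
        return DensityProfile(z_centers=centers,
                              values=self.acc[i] / self.n_frames,
                              bin_width=self.bin_width, label=self.labels[i],
                              n_frames=self.n_frames)


def leaflet_carbon_profiles(frames, topology: Topology, chains: ChainIndexing,
                            leaflets: LeafletMap, side: int,
                            bin_width: float = DEFAULT_BIN_WIDTH):
    """One NDP per carbon position, aggregated over the leaflet's lipids."""
    atoms, positions = carbon_position_table(topology, chains, leaflets, side)
    labels, n1, n2 = _position_labels(topology, chains)
    z_edges = _global_z_edges(frames, bin_width)
    profiles = []
    for pos in range(n1 + n2):
        sel = atoms[positions == pos]
        profiles.append(density_profile(
            frames, sel, bin_width, z_edges=z_edges,
            label=f"{'top' if side > 0 else 'bottom'}:{labels[pos]}"))
    return profiles


def domat(frames, topology: Topology, chains: ChainIndexing,
          leaflets: LeafletMap, bin_width: float = DEFAULT_BIN_WIDTH
          ) -> CarbonMatrix:
    """Density-overlap matrix: Omega_ij for all cross-leaflet carbon pairs.

    Profiles are time-averaged first, then overlapped (the matrix is the
    overlap of time-averaged NDPs, not the average of per-frame
    overlaps).  Quadrant sums and the grand total are available through
    :meth:`CarbonMatrix.quadrant_sums`.
    """
    frames = list(frames)
    labels, n1, n2 = _position_labels(topology, chains)
    top_profiles = leaflet_carbon_profiles(frames, topology, chains, leaflets,
                                           +1, bin_width)
    bot_profiles = leaflet_carbon_profiles(frames, topology, chains, leaflets,
                                           -1, bin_width)
    k = n1 + n2
    values = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            values[i, j] = overlap_integral(top_profiles[i], bot_profiles[j])
    return CarbonMatrix(values=values, row_labels=labels, col_labels=labels,
                        n_sn1=n1, n_sn2=n2, units="A^-2")


def leaflet_mass_profiles(frames, topology: Topology, leaflets: LeafletMap,
                          bin_width: float = DEFAULT_BIN_WIDTH):
    """Whole-leaflet mass-density profiles (all leaflet atoms), amu/A^3."""
    labels = leaflets.atom_labels(topology)
    z_edges = _global_z_edges(frames, bin_width)
    out = {}
    for side, name in ((+1, "top"), (-1, "bottom")):
        sel = np.flatnonzero(labels == side)
        if sel.size == 0:
            raise ValueError(f"{name} leaflet is empty")
        out[name] = density_profile(frames, sel, bin_width,
                                    weights=topology.masses[sel],
                                    label=f"{name} leaflet mass density",
                                    z_edges=z_edges)
    return out["top"], out["bottom"]


def memit(frames, topology: Topology, leaflets: LeafletMap,
          bin_width: float = DEFAULT_BIN_WIDTH, variant: str = "membplugin"):
    """Leaflet mass-density overlap, the baseline interdigitation scalar.

    Two standard dimensionless variants are computed from the leaflet
    mass-density profiles rho_t(z), rho_b(z):

    - ``"min-ratio"``:   2 * integral min(rho_t, rho_b) dz
      / integral (rho_t + rho_b) dz -- the symmetric overlap fraction
      (1 for coincident profiles, 0 for disjoint ones).
    - ``"membplugin"`` (default): integral of the overlap parameter
      4 rho_t rho_b / (rho_t + rho_b)^2 weighted by the normalized total
      density w(z) = (rho_t + rho_b) / integral (rho_t + rho_b) dz --
      the MEMBPLUGIN Interdigitation-tool form, likewise 1 for
      coincident and 0 for disjoint profiles.

    Returns ``(value, report)`` where ``report`` maps each variant name
    to its value.
    """
    rt, rb = leaflet_mass_profiles(frames, topology, leaflets, bin_width)
    t, b = rt.values, rb.values
    dz = rt.bin_width
    total = (t + b).sum() * dz
    if total == 0:
        raise ValueError("leaflet density profiles are empty")
    report = {}
    report["min-ratio"] = float(2 * np.minimum(t, b).sum() * dz / total)
    s = t + b
    with np.errstate(invalid="ignore", divide="ignore"):
        ov = np.where(s > 0, 4 * t * b / s**2, 0.0)
    w = s / total
    report["membplugin"] = float((ov * w).sum() * dz)
    if variant not in report:
        raise ValueError(f"unknown memIT variant {variant!r}")
    return report[variant], report
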