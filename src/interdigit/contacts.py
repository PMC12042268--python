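"""Interleaflet carbon-carbon contact matrices (ccMat).

A contact is a pair of acyl-chain carbon atoms, one from a top-leaflet
lipid and one from a bottom-leaflet lipid, whose minimum-image distance
is within a cutoff (4 Angstrom by default).  The contact matrix is
indexed by chain-carbon position -- rows are top-leaflet carbons ordered
sn-1 C2 -> terminal then sn-2 C2 -> terminal, columns the same for the
bottom leaflet -- and each element is the (time-averaged) number of
contacts between those carbon positions, aggregated over all lipids.
The four quadrants resolve sn-1/sn-2 chain pairings.

Counting uses a periodic k-d tree (O(N log N)); the exhaustive O(N^2)
minimum-image enumeration lives in the test suite as the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import ChainIndexing, Frame, LeafletMap, Topology, wrap_coords

DEFAULT_CUTOFF = 4.0  # Angstrom


@dataclass
class CarbonMatrix:
    """Rectangular matrix over (top carbon position, bottom carbon position).

    ``values[i, j]`` refers to row label ``row_labels[i]`` and column
    label ``col_labels[j]``; positions 0..n_sn1-1 are the sn-1 chain
    (glycerol-proximal to terminal), positions n_sn1.. are the sn-2
    chain.  ``units`` is ``"contacts/frame"`` for ccMat or ``"A^-2"``
    for density-overlap matrices.
    """

    values: np.ndarray
    row_labels: list
    col_labels: list
    n_sn1: int
    n_sn2: int
    units: str = "contacts/frame"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = self.n_sn1 + self.n_sn2
        if self.values.shape != (expected, expected):
            raise ValueError("matrix shape inconsistent with chain lengths")
        if np.any(self.values < 0):
            raise ValueError("matrix entries must be non-negative")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def quadrant_sums(self) -> dict:
        """Sums over the four sn-1/sn-2 quadrants plus the grand total."""
        k = self.n_sn1
        v = self.values
        out = {
            "sn1-sn1": float(v[:k, :k].sum()),
            "sn1-sn2": float(v[:k, k:].sum()),
            "sn2-sn1": float(v[k:, :k].sum()),
            "sn2-sn2": float(v[k:, k:].sum()),
        }
        out["total"] = self.total
        return out

    def transposed(self) -> "CarbonMatrix":
        """Matrix with leaflet roles swapped (rows <-> columns)."""
        return CarbonMatrix(values=self.values.T.copy(),
                            row_labels=list(self.col_labels),
                            col_labels=list(self.row_labels),
                            n_sn1=self.n_sn1, n_sn2=self.n_sn2, units=self.units)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.row_labels,
                            columns=self.col_labels)


def carbon_position_table(topology: Topology, chains: ChainIndexing,
                          leaflets: LeafletMap, side: int):
    """(atom indices, position indices) for one leaflet's chain carbons.

    Position index runs sn-1 C2..terminal then sn-2 C2..terminal and is
    shared by all lipids of the leaflet.
    """
    n1, n2 = chains.chain_lengths()
    resids = leaflets.top_resids if side > 0 else leaflets.bottom_resids
    atoms, positions = [], []
    for resid in resids:
        atoms.extend(chains.sn1[resid])
        positions.extend(range(n1))
        atoms.extend(chains.sn2[resid])
        positions.extend(range(n1, n1 + n2))
    return np.asarray(atoms, dtype=int), np.asarray(positions, dtype=int)


def _position_labels(topology: Topology, chains: ChainIndexing):
    n1, n2 = chains.chain_lengths()
    resid = chains.resids[0]
    labels = [f"sn1:{topology.names[i]}" for i in chains.sn1[resid]]
    labels += [f"sn2:{topology.names[i]}" for i in chains.sn2[resid]]
    return labels, n1, n2


def count_contacts(frame: Frame, topology: Topology, chains: ChainIndexing,
                   leaflets: LeafletMap, cutoff: float = DEFAULT_CUTOFF
                   ) -> CarbonMatrix:
    """Single-frame contact matrix at the given minimum-image cutoff.

    Each qualifying cross-leaflet carbon pair contributes exactly 1
    regardless of separation (binary contact).  Raises if the cutoff
    exceeds half the smallest box length, where the minimum-image
    convention breaks down.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff > frame.box.min() / 2:
        raise ValueError(
            f"cutoff {cutoff} A exceeds half the smallest box length "
            f"({frame.box.min() / 2:.2f} A); minimum image invalid")
    labels, n1, n2 = _position_labels(topology, chains)
    top_atoms, top_pos = carbon_position_table(topology, chains, leaflets, +1)
    bot_atoms, bot_pos = carbon_position_table(topology, chains, leaflets, -1)
    box = frame.box
    tc = wrap_coords(frame.coords[top_atoms], box)
    bc = wrap_coords(frame.coords[bot_atoms], box)
    values = np.zeros((n1 + n2, n1 + n2))
    tree = cKDTree(bc, boxsize=box)
    for ti, neighbours in enumerate(tree.query_ball_point(tc, r=cutoff)):
        if neighbours:
            np.add.at(values, (top_pos[ti], bot_pos[neighbours]), 1.0)
    return CarbonMatrix(values=values, row_labels=labels, col_labels=labels,
                        n_sn1=n1, n_sn2=n2, units="contacts/frame")


def average_ccmat(frames, topology: Topology, chains: ChainIndexing,
                  leaflets: LeafletMap, cutoff: float = DEFAULT_CUTOFF):
    """Time-averaged contact matrix plus the per-frame total series.

    Returns ``(CarbonMatrix, totals)`` where ``totals[k]`` is the grand
    total of frame k's matrix (the series handed to the dynamics layer).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("at least one frame is required")
    acc = None
    totals = np.empty(len(frames))
    for k, f in enumerate(frames):
        m = count_contacts(f, topology, chains, leaflets, cutoff)
        totals[k] = m.total
        acc = m.values if acc is None else acc + m.values
        template = m
    avg = CarbonMatrix(values=acc / len(frames),
                       row_labels=template.row_labels,
                       col_labels=template.col_labels,
                       n_sn1=template.n_sn1, n_sn2=template.n_sn2,
                       units="contacts/frame")
    return avg, totals
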