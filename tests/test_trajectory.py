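"""Topology/trajectory reading, chain indexing, centering and leaflets."""

import numpy as np
import pytest

from interdigit import Bilayer, FixtureSpec, Frame, Topology
from interdigit.core import BOTTOM, TOP, TopologyError
from interdigit.synth import make_gaussian_bilayer, write_fixture
from interdigit.trajectory import (assign_leaflets, center_frame, index_chains,
                                   load_topology, load_trajectory,
                                   unwrap_molecules)


def _dppc_like_names(n_carbons=15):
    # headgroup + glycerol stub, then full CHARMM chain naming
    names = ["P", "C1", "C2", "C3"]
    names += [f"C2{k}" for k in range(2, n_carbons + 2)]
    names += [f"C3{k}" for k in range(2, n_carbons + 2)]
    return names


def _topology_from_names(names_per_lipid, n_lipids=2):
    names, resids = [], []
    for li in range(n_lipids):
        names.extend(names_per_lipid)
        resids.extend([li + 1] * len(names_per_lipid))
    n = len(names)
    return Topology(names=names, types=["X"] * n, masses=[12.0] * n,
                    charges=[0.0] * n, resids=resids,
                    resnames=["DPPC"] * n)


class TestChainIndexing:
    def test_dppc_chains_run_c2_to_c16(self):
        """16:0 chains: 15 chain carbons C22-C216 / C32-C316 per chain."""
        top = _topology_from_names(_dppc_like_names(15))
        chains = index_chains(top)
        assert chains.chain_lengths() == (15, 15)
        for resid in chains.resids:
            sn2_names = [top.names[i] for i in chains.sn2[resid]]
            assert sn2_names[0] == "C22" and sn2_names[-1] == "C216"
            sn1_names = [top.names[i] for i in chains.sn1[resid]]
            assert sn1_names[0] == "C32" and sn1_names[-1] == "C316"

    def test_asymmetric_chains(self):
        """Mixed-chain lipid: sn-1 ends at C314, sn-2 at C218."""
        names = ["P"] + [f"C2{k}" for k in range(2, 19)]
        names += [f"C3{k}" for k in range(2, 15)]
        top = _topology_from_names(names, n_lipids=1)
        chains = index_chains(top)
        assert chains.chain_lengths() == (13, 17)
        assert str(top.names[chains.sn1[1][-1]]) == "C314"
        assert str(top.names[chains.sn2[1][-1]]) == "C218"

    def test_non_contiguous_chain_raises(self):
        names = ["P", "C22", "C23", "C25", "C32", "C33", "C34"]  # C24 missing
        top = _topology_from_names(names, n_lipids=1)
        with pytest.raises(TopologyError, match="contiguous"):
            index_chains(top)

    def test_fixture_lipids_index_to_spec_lengths(self, gauss_system):
        assert gauss_system.chains.chain_lengths() == (4, 4)


class TestCentering:
    def test_methyl_com_is_zero_after_centering(self, rng):
        spec = FixtureSpec(n_frames=1, seed=3)
        top, frames = make_gaussian_bilayer(spec)
        chains = index_chains(top)
        f = frames[0].translated([0.0, 0.0, 4.7])
        centered = center_frame(f, top, chains)
        idx = chains.terminal_methyl_indices()
        com = np.average(centered.coords[idx, 2], weights=top.masses[idx])
        assert abs(com) < 1e-9
        # x, y untouched
        np.testing.assert_array_equal(centered.coords[:, :2], f.coords[:, :2])

    def test_centering_is_idempotent(self):
        spec = FixtureSpec(n_frames=1, seed=5)
        top, frames = make_gaussian_bilayer(spec)
        chains = index_chains(top)
        once = center_frame(frames[0], top, chains)
        twice = center_frame(once, top, chains)
        np.testing.assert_array_equal(once.coords, twice.coords)


class TestLeaflets:
    def test_construction_labels_recovered(self, gauss_system):
        """Leaflet assignment recovers the generator's leaflet membership."""
        top = gauss_system.topology
        lm = gauss_system.leaflets
        n = len(top.lipid_resids)
        # generator builds the top leaflet first (lowest resids)
        assert list(lm.top_resids) == list(top.lipid_resids[: n // 2])
        assert list(lm.bottom_resids) == list(top.lipid_resids[n // 2:])

    def test_invariant_under_xy_translation(self):
        spec = FixtureSpec(n_frames=2, seed=9)
        top, frames = make_gaussian_bilayer(spec)
        chains = index_chains(top)
        frames = [center_frame(f, top, chains) for f in frames]
        base = assign_leaflets(top, frames)
        moved = [f.translated([13.7, -4.1, 0.0]) for f in frames]
        assert assign_leaflets(top, moved).labels == base.labels

    def test_single_frame_input(self):
        spec = FixtureSpec(n_frames=1, seed=9)
        top, frames = make_gaussian_bilayer(spec)
        chains = index_chains(top)
        lm = assign_leaflets(top, center_frame(frames[0], top, chains))
        sides = set(lm.labels.values())
        assert sides == {TOP, BOTTOM}

    def test_empty_leaflet_raises(self):
        spec = FixtureSpec(n_frames=1, seed=9)
        top, frames = make_gaussian_bilayer(spec)
        shifted = frames[0].translated([0, 0, 200.0])  # everything above z=0
        with pytest.raises(Exception):
            assign_leaflets(top, shifted)


class TestFileRoundTrip:
    def test_psf_dcd_round_trip(self, tmp_path, gauss_spec):
        """Fixtures written as PSF+DCD reload through the real reader path."""
        top, frames = make_gaussian_bilayer(gauss_spec)
        psf, dcd = tmp_path / "fix.psf", tmp_path / "fix.dcd"
        write_fixture(top, frames, psf, dcd, tmp_path / "fix.txt")
        top2, frames2 = load_trajectory(psf, dcd)
        assert top2.n_atoms == top.n_atoms
        assert list(top2.names) == list(top.names)
        np.testing.assert_allclose(top2.masses, top.masses, atol=1e-4)
        assert top2.n_lipids == 2 * gauss_spec.lipids_per_leaflet
        assert len(frames2) == len(frames)
        for f, g in zip(frames, frames2):
            np.testing.assert_allclose(g.coords, f.coords, atol=1e-4)
            np.testing.assert_allclose(g.box, f.box, atol=1e-4)

    def test_loaded_fixture_analyzes_identically(self, tmp_path, gauss_spec):
        top, frames = make_gaussian_bilayer(gauss_spec)
        psf, dcd = tmp_path / "fix.psf", tmp_path / "fix.dcd"
        write_fixture(top, frames, psf, dcd)
        direct = Bilayer(top, frames)
        loaded = Bilayer.from_files(psf, dcd)
        m1, _ = direct.ccmat()
        m2, _ = loaded.ccmat()
        # DCD stores float32 coordinates
        np.testing.assert_allclose(m2.values, m1.values, atol=1e-10)

    def test_water_only_topology_rejected(self, tmp_path):
        n = 8
        top = Topology(names=["OH2"] * n, types=["OT"] * n,
                       masses=[15.9994] * n, charges=[0.0] * n,
                       resids=list(range(1, n + 1)), resnames=["TIP3"] * n)
        from interdigit.synth import write_psf
        path = tmp_path / "waters.psf"
        write_psf(top, path)
        with pytest.raises(TopologyError, match="zero lipid"):
            load_topology(path)


class TestUnwrap:
    def test_split_molecule_is_rejoined(self):
        spec = FixtureSpec(n_frames=1, seed=13)
        top, frames = make_gaussian_bilayer(spec)
        f = frames[0]
        # push one lipid's second atom across the x boundary
        resid = top.lipid_resids[0]
        atoms = top.atoms_of_residue(resid)
        broken = f.coords.copy()
        broken[atoms[1], 0] += f.box[0]
        rejoined = unwrap_molecules(Frame(broken, f.box), top)
        np.testing.assert_allclose(rejoined.coords[atoms[1]],
                                   f.coords[atoms[1]], atol=1e-9)
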