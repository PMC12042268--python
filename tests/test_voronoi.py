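"""Periodic Voronoi tessellation, interface harvesting, and nISA."""

import numpy as np
import pytest

from interdigit import Bilayer, FixtureSpec, Frame, Topology
from interdigit.core import BOTTOM, TOP, LeafletMap
from interdigit.voronoi import (chain_contributions, export_mesh,
                                intensity_map, interface_mesh, load_obj,
                                mesh_obj_area, nisa, tessellate)
from oracles import brute_force_voronoi


def _point_topology(n, resname="LIP", name="C22"):
    return Topology(names=[name] * n, types=["C"] * n, masses=[12.0] * n,
                    charges=[0.0] * n, resids=list(range(1, n + 1)),
                    resnames=[resname] * n)


class TestTessellation:
    def test_two_points_unit_box(self):
        """Two generators at z = +-0.25: equal half-volumes and two unit
        cross faces (one at z = 0, one through the periodic boundary)."""
        top = _point_topology(2)
        frame = Frame(coords=[[0.5, 0.5, 0.75], [0.5, 0.5, 0.25]],
                      box=[1.0, 1.0, 1.0])
        diagram = tessellate(frame, include=np.ones(2, dtype=bool), jitter=0.0)
        np.testing.assert_allclose(diagram.volumes, [0.5, 0.5], rtol=1e-9)
        cross = diagram.face_atom_a != diagram.face_atom_b
        area = float((diagram.face_area * diagram.face_weight)[cross].sum())
        assert area == pytest.approx(2.0, rel=1e-9)

    def test_volume_conservation_random(self, rng):
        n = 40
        box = np.array([14.0, 11.0, 19.0])
        frame = Frame(coords=rng.uniform(0, 1, (n, 3)) * box, box=box)
        diagram = tessellate(frame, include=np.ones(n, dtype=bool))
        assert diagram.total_volume == pytest.approx(frame.volume, rel=1e-9)

    def test_volume_conservation_fixture(self, gauss_system):
        f = gauss_system.frames[0]
        diagram = tessellate(f, gauss_system.topology)
        assert diagram.total_volume == pytest.approx(f.volume, rel=1e-6)

    @pytest.mark.parametrize("n,seed", [(8, 0), (14, 1), (20, 2)])
    def test_matches_halfspace_oracle(self, n, seed):
        """Neighbor graph and per-pair face areas equal the brute-force
        half-space-intersection construction."""
        rng = np.random.default_rng(seed)
        box = np.array([10.0, 9.0, 11.0])
        pts = rng.uniform(0.05, 0.95, (n, 3)) * box
        frame = Frame(coords=pts, box=box)
        diagram = tessellate(frame, include=np.ones(n, dtype=bool), jitter=0.0)
        ref_vol, ref_pairs = brute_force_voronoi(pts, box)
        np.testing.assert_allclose(diagram.volumes, ref_vol, rtol=1e-6)
        got = {}
        for a, b, ar, w in zip(diagram.face_atom_a, diagram.face_atom_b,
                               diagram.face_area, diagram.face_weight):
            key = (min(a, b), max(a, b))
            got[key] = got.get(key, 0.0) + ar * w
        ref = {k: v for k, v in ref_pairs.items() if v > 1e-7}
        got = {k: v for k, v in got.items() if v > 1e-7}
        assert set(got) == set(ref)
        for k in ref:
            assert got[k] == pytest.approx(ref[k], rel=1e-6, abs=1e-9)

    def test_coincident_generators_warn(self):
        frame = Frame(coords=[[1, 1, 1], [1, 1, 1], [3, 3, 3], [5, 2, 4]],
                      box=[8.0, 8.0, 8.0])
        with pytest.warns(UserWarning, match="coincident"):
            tessellate(frame, include=np.ones(4, dtype=bool))

    def test_too_few_generators(self):
        frame = Frame(coords=[[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]],
                      box=[8.0, 8.0, 8.0])
        with pytest.raises(ValueError, match="generators"):
            tessellate(frame, include=np.array([True, False]))


class TestInterfaceAndNisa:
    def test_flat_lattice_nisa_is_one(self, flat_system):
        """Flat, non-interdigitated interface: nISA = 1 to 1e-6."""
        value = flat_system.nisa_series().nisa[0]
        assert value == pytest.approx(1.0, abs=1e-6)

    def test_flat_mesh_area_equals_axy(self, flat_system):
        mesh = flat_system.interface_mesh(0)
        assert mesh.total_area == pytest.approx(mesh.axy, rel=1e-6)
        assert np.all(mesh.areas > 0)

    def test_mesh_owners_are_cross_leaflet_lipid_atoms(self, gauss_system):
        mesh = gauss_system.interface_mesh(0)
        labels = gauss_system.leaflets.atom_labels(gauss_system.topology)
        assert np.all(labels[mesh.atom_top] == TOP)
        assert np.all(labels[mesh.atom_bottom] == BOTTOM)

    def test_separated_slabs_give_empty_mesh(self):
        """Leaflets fully separated by water generators share no faces."""
        rng = np.random.default_rng(6)
        box = np.array([12.0, 12.0, 40.0])
        n = 12
        nw = 90
        xy = rng.uniform(0, 12, (2 * n + nw, 2))
        z = np.concatenate([rng.uniform(14, 17, n),       # top slab
                            rng.uniform(-17, -14, n),     # bottom slab
                            rng.uniform(-9, 9, 60),       # waters between
                            rng.uniform(18, 19.5, 15),    # waters beyond
                            rng.uniform(-19.5, -18, 15)])
        coords = np.column_stack([xy, z])
        topology = Topology(
            names=["C22"] * (2 * n) + ["OH2"] * nw,
            types=["C"] * (2 * n) + ["OT"] * nw,
            masses=[12.0] * (2 * n) + [16.0] * nw,
            charges=[0.0] * (2 * n + nw),
            resids=list(range(1, 2 * n + nw + 1)),
            resnames=["LIP"] * (2 * n) + ["TIP3"] * nw)
        frame = Frame(coords=coords, box=box)
        leaflets = LeafletMap({r: TOP for r in range(1, n + 1)}
                              | {r: BOTTOM for r in range(n + 1, 2 * n + 1)})
        diagram = tessellate(frame, topology)
        with pytest.warns(UserWarning, match="empty"):
            mesh = interface_mesh(diagram, leaflets, topology)
        assert len(mesh) == 0
        assert nisa(mesh) == 0.0

    def test_nisa_invariant_under_xy_translation_and_rotation(self, flat_spec):
        spec = FixtureSpec(lipids_per_leaflet=9, n_frames=1, seed=17,
                           delta=1.5)
        bl = Bilayer.from_spec(spec)
        base = bl.nisa_series().nisa[0]
        f = bl.frames[0]
        shifted = Bilayer(bl.topology, [f.translated([5.3, -2.2, 0.0])],
                          chains=bl.chains, leaflets=bl.leaflets,
                          prepare=False)
        assert shifted.nisa_series().nisa[0] == pytest.approx(base, rel=1e-4)
        # 90 degree rotation about z (Lx = Ly)
        c = f.coords.copy()
        rot = np.column_stack([-c[:, 1] + f.box[1], c[:, 0], c[:, 2]])
        rotated = Bilayer(bl.topology, [Frame(rot, f.box, f.time)],
                          chains=bl.chains, leaflets=bl.leaflets,
                          prepare=False)
        assert rotated.nisa_series().nisa[0] == pytest.approx(base, rel=1e-4)


class TestChainContributions:
    def test_fractions_partition_unity(self, gauss_system):
        mesh = gauss_system.interface_mesh(0)
        frac = chain_contributions(mesh, gauss_system.chains,
                                   gauss_system.topology.n_atoms)
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0 for v in frac.values())

    def test_sn2_only_penetration_dominates(self):
        """When only the sn-2 terminal carbon penetrates, the sn-2/sn-2
        quadrant owns the largest share of the interface."""
        # sn-2 penetrates (profile ending below the midplane), sn-1 stays out
        sn2_profile = np.array([12.0, 8.0, 4.0, -3.0])
        spec = FixtureSpec(n_frames=2, seed=23, sigma=1.0,
                           depth_profile=np.array([12.0, 9.0, 6.0, 3.0]))
        top, frames = _make_asymmetric(spec, sn2_profile)
        bl = Bilayer(top, frames)
        mesh = bl.interface_mesh(0)
        frac = chain_contributions(mesh, bl.chains, top.n_atoms)
        chain_pairs = {k: v for k, v in frac.items() if k != "other"}
        assert max(chain_pairs, key=chain_pairs.get) == "sn2-sn2"


def _make_asymmetric(spec, sn2_profile):
    """Gaussian fixture whose sn-2 chain uses a deeper depth profile."""
    from interdigit import synth

    rng = np.random.default_rng(spec.seed)
    n = spec.lipids_per_leaflet
    lx, ly, lz = spec.box
    means_sn1 = spec.chain_means(spec.n_sn1)
    means_sn2 = np.asarray(sn2_profile, dtype=float)
    z_head = spec.head_depth + 3.0
    waters = synth._water_lattice_layers(spec, z_head + 1.0)
    frames = []
    for k in range(spec.n_frames):
        coords = []
        for side in (+1, -1):
            for li in range(n):
                xy = rng.uniform([0, 0], [lx, ly])
                coords.append([xy[0], xy[1],
                               side * (z_head + rng.normal(0, spec.sigma))])
                for means in (means_sn1, means_sn2):
                    z = side * (means + rng.normal(0, spec.sigma, len(means)))
                    z = side * np.sort(side * z)[::-1]
                    for m_i in range(len(means)):
                        cxy = xy + rng.normal(0, 1.0, 2)
                        coords.append([cxy[0], cxy[1], z[m_i]])
        frames.append(Frame(np.concatenate([np.asarray(coords), waters]),
                            np.asarray(spec.box), float(k)))
    top = synth._build_topology(2 * n, spec.n_sn1, spec.n_sn2, len(waters))
    return top, frames


class TestMeshExports:
    def test_obj_round_trip_area(self, tmp_path, flat_system):
        mesh = flat_system.interface_mesh(0)
        path = tmp_path / "mesh.obj"
        export_mesh(mesh, path)
        verts, tris = load_obj(path)
        assert len(tris) > 0
        assert mesh_obj_area(path) == pytest.approx(mesh.total_area, rel=1e-5)

    def test_obj_vertices_round_trip_precision(self, tmp_path, gauss_system):
        mesh = gauss_system.interface_mesh(0)
        path = tmp_path / "mesh.obj"
        export_mesh(mesh, path)
        verts, _ = load_obj(path)
        all_in = np.concatenate([v for v in mesh.vertices])
        # every face vertex appears in the file to 1e-4 A
        sample = all_in[:: max(1, len(all_in) // 50)]
        for v in sample:
            assert np.min(np.linalg.norm(verts - v, axis=1)) < 1e-4

    def test_intensity_map_flat_interface_is_zero(self, flat_system):
        mesh = flat_system.interface_mesh(0)
        values, (xe, ye) = intensity_map(mesh, resolution=2.0)
        assert np.nanmax(np.abs(values)) < 1e-3  # faces sit at z = 0
        assert values.shape == (len(xe) - 1, len(ye) - 1)

    def test_intensity_map_marks_deep_faces(self, gauss_system):
        mesh = gauss_system.interface_mesh(0)
        values, _ = intensity_map(mesh, resolution=1.0)
        depth = np.array([np.abs(v[:, 2]).mean() for v in mesh.vertices])
        assert values.max() <= depth.max() + 1e-9
        assert values.max() > 0

    def test_intensity_map_validates_resolution(self, flat_system):
        mesh = flat_system.interface_mesh(0)
        with pytest.raises(ValueError):
            intensity_map(mesh, resolution=0.0)
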