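"""Geometry metrics: superposition, salt bridges, ring assemblies, pores.

All fixtures are synthetic assemblies constructed in memory; no
deposited structures are required.
"""

import numpy as np
import pytest

from pqinr.structure import (
    AtomModel,
    RingAssembly,
    assembly_from_symmetry,
    find_salt_bridges,
    pore_profile,
    superpose_rmsd,
)

from conftest import quaternion_superpose_rmsd


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def make_model(records):
    """AtomModel from (element, name, res_name, res_id, chain, xyz) rows."""
    el, nm, rn, ri, ch, xyz = zip(*records)
    return AtomModel(
        elements=np.array(el), names=np.array(nm), res_names=np.array(rn),
        res_ids=np.array(ri), chains=np.array(ch),
        coords=np.array(xyz, float), occupancies=np.ones(len(el)),
    )


class TestSuperposeRMSD:
    def test_identical_coordinates_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(20, 3)) * 10
        rmsd, n = superpose_rmsd(a, a.copy())
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert n == 20

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(30, 3)) * 15
        rot = rotation_matrix([1, 2, 3], 1.1)
        b = a @ rot.T + np.array([5.0, -3.0, 12.0])
        rmsd, _ = superpose_rmsd(a, b)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.normal(size=(10, 3)) * 8
            b = rng.normal(size=(10, 3)) * 8
            rmsd, _ = superpose_rmsd(a, b)
            assert rmsd == pytest.approx(quaternion_superpose_rmsd(a, b),
                                         abs=1e-9)

    def test_pruning_is_monotone(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(25, 3)) * 10
        b = a + rng.normal(size=(25, 3)) * 0.3
        b[5] += 8.0  # one outlier pair
        rmsd_all, n_all = superpose_rmsd(a, b)
        rmsd_pruned, n_pruned = superpose_rmsd(a, b, prune_cutoff=2.0)
        assert rmsd_pruned <= rmsd_all
        assert n_pruned == n_all - 1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestSaltBridges:
    @staticmethod
    def dimer(separation):
        """An Asp (chain A) carboxylate and a Lys (chain B) amine."""
        return make_model([
            ("O", "OD1", "ASP", 68, "A", (0.0, 0.0, 0.0)),
            ("O", "OD2", "ASP", 68, "A", (-0.5, 1.0, 0.0)),
            ("C", "CB", "ASP", 68, "A", (-1.0, 0.0, 0.0)),
            ("N", "NZ", "LYS", 166, "B", (separation, 0.0, 0.0)),
            ("C", "CB", "LYS", 166, "B", (separation + 1.5, 0.0, 0.0)),
        ])

    def test_pair_within_cutoff_found(self):
        bridges = find_salt_bridges(self.dimer(3.5), "A", "B")
        assert len(bridges) == 1
        b = bridges[0]
        assert (b["acidic"]["res_name"], b["acidic"]["res_id"]) == ("ASP", 68)
        assert (b["basic"]["res_name"], b["basic"]["res_id"]) == ("LYS", 166)
        assert b["distance"] == pytest.approx(3.5)

    def test_pair_beyond_cutoff_missed(self):
        assert find_salt_bridges(self.dimer(4.5), "A", "B") == []

    def test_symmetric_in_chain_order(self):
        m = self.dimer(3.2)
        assert (find_salt_bridges(m, "A", "B")
                == find_salt_bridges(m, "B", "A"))

    def test_missing_sidechain_atoms_skipped(self):
        m = make_model([
            ("C", "CB", "ASP", 10, "A", (0.0, 0.0, 0.0)),  # no carboxylate O
            ("N", "NZ", "LYS", 20, "B", (3.0, 0.0, 0.0)),
        ])
        assert find_salt_bridges(m, "A", "B") == []

    def test_histidine_only_with_flag(self):
        m = make_model([
            ("O", "OE1", "GLU", 5, "A", (0.0, 0.0, 0.0)),
            ("N", "NE2", "HIS", 9, "B", (3.0, 0.0, 0.0)),
        ])
        assert find_salt_bridges(m, "A", "B") == []
        assert len(find_salt_bridges(m, "A", "B", include_his=True)) == 1

    def test_absent_chain_rejected(self):
        with pytest.raises(ValueError):
            find_salt_bridges(self.dimer(3.0), "A", "Z")


def ring_of_spheres(n=8, ring_radius=40.0, atom_radius=1.7, jitter_axis=None):
    """n single-atom 'protomers' evenly spaced on a circle in the xy plane."""
    records = []
    for i in range(n):
        phi = 2 * np.pi * i / n
        xyz = (ring_radius * np.cos(phi), ring_radius * np.sin(phi), 0.0)
        records.append(("C", "CA", "GLY", 1, chr(ord("A") + i), xyz))
    return make_model(records)


class TestPoreProfile:
    def test_ring_of_spheres_geometry(self):
        r_ring, r_atom = 40.0, 1.7
        model = ring_of_spheres(ring_radius=r_ring, atom_radius=r_atom)
        asm = assembly_from_symmetry(model)
        prof = pore_profile(asm, step=0.5)
        # at the ring plane the probe reaches ring radius - vdw radius
        assert prof["min_pore_diameter"] == pytest.approx(
            2 * (r_ring - r_atom), rel=1e-6)
        assert prof["max_outer_diameter"] == pytest.approx(
            2 * (r_ring + r_atom), rel=1e-6)

    def test_doubling_coordinates_doubles_radii(self):
        model = ring_of_spheres(ring_radius=30.0)
        asm1 = assembly_from_symmetry(model)
        model2 = make_model([
            (e, n, rn, ri, ch, tuple(2 * np.asarray(x)))
            for e, n, rn, ri, ch, x in zip(
                model.elements, model.names, model.res_names,
                model.res_ids, model.chains, model.coords)])
        asm2 = assembly_from_symmetry(model2)
        p1 = pore_profile(asm1, step=0.5)
        p2 = pore_profile(asm2, step=0.5)
        # pore radius doubles up to the (unchanged) vdw radius offset
        r1 = p1["min_pore_diameter"] / 2 + 1.7
        r2 = p2["min_pore_diameter"] / 2 + 1.7
        assert r2 == pytest.approx(2 * r1, rel=1e-6)

    def test_agrees_with_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(60, 3)) * 20
        vdw = rng.uniform(1.2, 2.0, 60)
        asm = RingAssembly(coords=coords, vdw=vdw,
                           protomer_centroids=coords[:2],
                           axis_point=np.zeros(3),
                           axis_direction=np.array([0.0, 0.0, 1.0]),
                           order=2)
        prof = pore_profile(asm, step=2.0)
        for zi, ri in zip(prof["z"], prof["radius"]):
            centre = np.array([0.0, 0.0, zi])
            best = min(np.linalg.norm(centre - coords[j]) - vdw[j]
                       for j in range(len(coords)))
            assert ri == pytest.approx(best, abs=1e-6)

    def test_rotation_about_axis_invariance(self):
        model = ring_of_spheres()
        asm = assembly_from_symmetry(model)
        rot = rotation_matrix([0, 0, 1], 0.7)
        asm_rot = RingAssembly(coords=asm.coords @ rot.T, vdw=asm.vdw,
                               protomer_centroids=asm.protomer_centroids @ rot.T,
                               axis_point=np.zeros(3),
                               axis_direction=np.array([0.0, 0.0, 1.0]),
                               order=asm.order)
        p1 = pore_profile(asm, step=1.0)
        p2 = pore_profile(asm_rot, step=1.0)
        np.testing.assert_allclose(p1["radius"], p2["radius"], atol=1e-9)

    def test_empty_assembly_rejected(self):
        asm = RingAssembly(coords=np.zeros((0, 3)), vdw=np.zeros(0),
                           protomer_centroids=np.zeros((2, 3)),
                           axis_point=np.zeros(3),
                           axis_direction=np.array([0, 0, 1.0]), order=2)
        with pytest.raises(ValueError):
            pore_profile(asm)


class TestAssemblyFromSymmetry:
    def test_preexpanded_ring_passthrough(self):
        model = ring_of_spheres(n=8)
        asm = assembly_from_symmetry(model)
        assert asm.order == 8
        assert asm.diagnostics["closed_ring"]

    def test_eightfold_operators_recover_axis(self):
        # single protomer (a small blob) + 8-fold rotation operators about
        # a known tilted axis
        rng = np.random.default_rng(5)
        axis = np.array([0.2, -0.1, 1.0])
        axis /= np.linalg.norm(axis)
        # place the blob off-axis
        perp = np.cross(axis, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        blob = 35.0 * perp + rng.normal(size=(12, 3)) * 2.0
        records = [("C", "CA", "GLY", i, "A", tuple(x))
                   for i, x in enumerate(blob)]
        model = make_model(records)
        ops = []
        for i in range(1, 8):
            r = rotation_matrix(axis, 2 * np.pi * i / 8)
            op = np.eye(4)
            op[:3, :3] = r
            ops.append(op)
        asm = assembly_from_symmetry(model, operators=ops)
        assert asm.order == 8
        assert asm.diagnostics["closed_ring"]
        cos = abs(float(asm.axis_direction @ axis))
        assert np.degrees(np.arccos(min(cos, 1.0))) < 0.5

    def test_crystal_symmetry_expansion_from_pdb_file(self, tmp_path):
        # synthetic crystal: one small protomer in P4 -> four copies
        # closing a ring about the c axis
        import gemmi

        st = gemmi.Structure()
        st.cell = gemmi.UnitCell(100, 100, 50, 90, 90, 90)
        st.spacegroup_hm = "P 4"
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(1, " ")
        for i, xyz in enumerate([(30.0, 5.0, 10.0), (32.0, 6.0, 11.0),
                                 (31.0, 4.0, 9.0)]):
            atom = gemmi.Atom()
            atom.name = "CA" if i == 0 else f"C{i}"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
        path = tmp_path / "synthetic_p4.pdb"
        st.write_pdb(str(path))

        m = AtomModel.from_file(path)
        assert len(m.coords) == 3
        asm = assembly_from_symmetry(m)
        assert asm.order == 4
        assert asm.diagnostics["closed_ring"]
        assert abs(asm.axis_direction @ np.array([0.0, 0.0, 1.0])) > 0.999

    def test_open_arrangement_reported_not_silently_accepted(self):
        # three collinear protomers cannot close a ring
        records = []
        for i, x in enumerate([0.0, 50.0, 100.0]):
            records.append(("C", "CA", "GLY", 1, chr(ord("A") + i),
                            (x, 0.0, 0.0)))
        asm = assembly_from_symmetry(make_model(records))
        assert not asm.diagnostics["closed_ring"]
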