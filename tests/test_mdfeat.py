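"""Structural observables against brute-force oracles on toy structures."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import random_toy_frame
from polphen.mdfeat import (PocketSpec, StructureFrame, backbone_dihedrals,
                            dihedral, extract_pair_distances,
                            min_residue_distance,
                            pocket_contacts, pocket_surface_area,
                            resolve_frame_range, superpose_rmsd)


class TestMinResidueDistance:
    def test_pythagorean_toy(self):
        frame = StructureFrame(names=["A", "B"], elements=["C", "C"],
                               residue_ids=[1, 2],
                               coords=[[0, 0, 0], [3, 4, 0]])
        assert min_residue_distance(frame, 1, 2) == pytest.approx(5.0)

    def test_symmetric_and_self_zero(self, rng):
        frame = random_toy_frame(rng)
        assert min_residue_distance(frame, 1, 3) == pytest.approx(
            min_residue_distance(frame, 3, 1))
        assert min_residue_distance(frame, 2, 2) == 0.0

    def test_heavy_atom_default_excludes_hydrogens(self):
        frame = StructureFrame(names=["C1", "H1", "C2"],
                               elements=["C", "H", "C"],
                               residue_ids=[1, 1, 2],
                               coords=[[0, 0, 0], [0, 0, 9], [0, 0, 10]])
        assert min_residue_distance(frame, 1, 2) == pytest.approx(10.0)
        assert min_residue_distance(frame, 1, 2, heavy_only=False) == pytest.approx(1.0)

    def test_missing_residue_raises(self, rng):
        with pytest.raises(KeyError):
            min_residue_distance(random_toy_frame(rng), 1, 99)

    def test_agrees_with_bruteforce_on_random_toys(self, rng):
        for _ in range(100):
            frame = random_toy_frame(rng)
            a, b = rng.choice(np.arange(1, 6), size=2, replace=False)
            ca = frame.residue_coords(a)
            cb = frame.residue_coords(b)
            brute = min(np.linalg.norm(p - q) for p in ca for q in cb)
            assert abs(min_residue_distance(frame, a, b) - brute) <= 1e-8


class TestExtractPairDistances:
    def test_pooled_mean_equals_concatenation_oracle(self, rng):
        replicates = [[random_toy_frame(rng) for _ in range(6)] for _ in range(3)]
        pairs = [("p12", 1, 2), ("p34", 3, 4)]
        series, pooled = extract_pair_distances(replicates, pairs,
                                                frame_range=None)
        for name, ra, rb in pairs:
            concat = np.concatenate([
                [min_residue_distance(f, ra, rb) for f in frames]
                for frames in replicates
            ])
            assert pooled[name] == pytest.approx(concat.mean())

    def test_last_half_window(self, rng):
        replicates = [[random_toy_frame(rng) for _ in range(7)]]
        series, _ = extract_pair_distances(replicates, [("p", 1, 2)],
                                           frame_range="last-half")
        assert len(series["p"][0]) == 4   # ceil(7/2) frames retained

    def test_pooling_order_invariant(self, rng):
        replicates = [[random_toy_frame(rng) for _ in range(4)] for _ in range(3)]
        _, pooled_a = extract_pair_distances(replicates, [("p", 1, 2)], None)
        _, pooled_b = extract_pair_distances(replicates[::-1], [("p", 1, 2)], None)
        assert pooled_a["p"] == pytest.approx(pooled_b["p"])

    def test_resolve_frame_range(self):
        assert resolve_frame_range(10, None) == slice(0, 10)
        assert resolve_frame_range(10, "last-half") == slice(5, 10)
        with pytest.raises(ValueError):
            resolve_frame_range(10, "middle")


class TestPocketContacts:
    def _two_residue_frame(self, d):
        return StructureFrame(names=["A", "B"], elements=["C", "C"],
                              residue_ids=[837, 841],
                              coords=[[0, 0, 0], [d, 0, 0]])

    def test_cutoff_boundary(self):
        spec = PocketSpec(residues=(837, 841))
        assert pocket_contacts(self._two_residue_frame(5.9), spec) == 1
        assert pocket_contacts(self._two_residue_frame(6.0), spec) == 1  # inclusive
        assert pocket_contacts(self._two_residue_frame(6.1), spec) == 0

    def test_matches_exhaustive_enumeration(self, rng):
        ids = tuple(range(1, 10))
        frame = random_toy_frame(rng, n_residues=9, atoms_per_residue=3)
        spec = PocketSpec(residues=ids)
        brute = sum(
            1
            for i in range(9) for j in range(i + 1, 9)
            if min_residue_distance(frame, ids[i], ids[j]) <= spec.contact_cutoff
        )
        assert pocket_contacts(frame, spec) == brute

    def test_monotone_in_cutoff(self, rng):
        frame = random_toy_frame(rng, n_residues=9, atoms_per_residue=3)
        ids = tuple(range(1, 10))
        counts = [pocket_contacts(frame, PocketSpec(residues=ids, contact_cutoff=c))
                  for c in (3.0, 6.0, 9.0, 20.0)]
        assert counts == sorted(counts)


class TestPocketSurfaceArea:
    def test_isolated_atom_analytic_sphere(self):
        frame = StructureFrame(names=["C"], elements=["C"], residue_ids=[1076],
                               coords=[[0.0, 0.0, 0.0]])
        spec = PocketSpec(residues=(1076,))
        area = pocket_surface_area(frame, spec)
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert abs(area - exact) / exact < 0.01

    def test_buried_atom_near_zero(self):
        # central atom enclosed by an octahedral cage of large spheres
        cage = np.array([[3, 0, 0], [-3, 0, 0], [0, 3, 0], [0, -3, 0],
                         [0, 0, 3], [0, 0, -3], [2, 2, 0], [-2, -2, 0],
                         [2, -2, 0], [-2, 2, 0], [0, 2, 2], [0, -2, -2],
                         [2, 0, 2], [-2, 0, -2], [0, 2, -2], [0, -2, 2]])
        frame = StructureFrame(
            names=[f"A{i}" for i in range(len(cage) + 1)],
            elements=["C"] + ["S"] * len(cage),
            residue_ids=[1076] + [2000] * len(cage),
            coords=np.vstack([[0.0, 0.0, 0.0], cage]),
        )
        area = pocket_surface_area(frame, PocketSpec(residues=(1076,)))
        assert area < 5.0

    def test_occlusion_monotone(self):
        def area_with_neighbor(d):
            frame = StructureFrame(names=["A", "B"], elements=["C", "C"],
                                   residue_ids=[1076, 1079],
                                   coords=[[0, 0, 0], [d, 0, 0]])
            return pocket_surface_area(frame, PocketSpec(residues=(1076, 1079)))
        areas = [area_with_neighbor(d) for d in (7.0, 4.0, 2.0)]
        assert areas[0] > areas[1] > areas[2]

    def test_unknown_element_rejected(self):
        frame = StructureFrame(names=["Q"], elements=["XX"], residue_ids=[1076],
                               coords=[[0, 0, 0]])
        with pytest.raises(ValueError):
            pocket_surface_area(frame, PocketSpec(residues=(1076,)))


class TestDihedrals:
    def test_planar_trans(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]) == pytest.approx(180.0)

    def test_planar_cis(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_cross_product_oracle(self, rng):
        for _ in range(100):
            p = rng.standard_normal((4, 3)) * 3
            b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            cosang = n1 @ n2 / (np.linalg.norm(n1) * np.linalg.norm(n2))
            expected = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            sign = np.sign(np.cross(n1, n2) @ b2) or 1.0
            got = dihedral(*p)
            assert abs(abs(got) - expected) <= 1e-8
            if abs(expected) > 1e-6 and abs(expected - 180) > 1e-6:
                assert np.sign(got) == sign

    def test_backbone_phi_psi_table(self):
        # three-residue strand with ideal-ish geometry
        coords = []
        names = []
        resids = []
        for i in range(3):
            base = np.array([3.8 * i, 0.0, 0.0])
            for name, off in (("N", [0.0, 0.0, 0.0]),
                              ("CA", [1.46, 0.0, 0.0]),
                              ("C", [2.0, 1.4, 0.3])):
                names.append(name)
                resids.append(i + 1)
                coords.append(base + off)
        frame = StructureFrame(names=names, elements=["N", "C", "C"] * 3,
                               residue_ids=resids, coords=np.array(coords))
        table = backbone_dihedrals(frame, [2])
        assert set(table[2]) == {"phi", "psi"}
        phi_oracle = dihedral(coords[2], coords[3], coords[4], coords[5])
        assert table[2]["phi"] == pytest.approx(phi_oracle)

    def test_missing_backbone_atom_raises(self, rng):
        frame = random_toy_frame(rng)
        with pytest.raises(KeyError):
            backbone_dihedrals(frame, [1])


class TestStructureIO:
    PDB = (
        "ATOM      1  N   ALA A   8      11.104   6.134  -6.504  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   8      11.639   6.071  -5.147  1.00  0.00           C\n"
        "ATOM      3  C   ALA A   8      12.685   7.182  -5.033  1.00  0.00           C\n"
        "ATOM      4  O   ALA A   8      13.339   7.378  -4.004  1.00  0.00           O\n"
        "ATOM      5  N   GLY A   9      12.850   7.926  -6.123  1.00  0.00           N\n"
        "ATOM      6  CA  GLY A   9      13.832   8.984  -6.144  1.00  0.00           C\n"
        "ATOM      7  C   GLY A   9      13.217  10.279  -5.644  1.00  0.00           C\n"
        "ATOM      8  O   GLY A   9      12.016  10.331  -5.380  1.00  0.00           O\n"
        "END\n"
    )

    def test_pdb_roundtrip_with_author_offset(self, tmp_path):
        import mdtraj as md

        from polphen.mdfeat import frames_from_mdtraj

        path = tmp_path / "toy.pdb"
        path.write_text(self.PDB)
        traj = md.load(str(path))
        # file numbering 8/9 maps to author numbering 1083/1084
        (frame,) = frames_from_mdtraj(traj, resid_offset=1075)
        assert sorted(set(frame.residue_ids)) == [1083, 1084]
        ca = frame.coords[(frame.residue_ids == 1083) & (frame.names == "CA")]
        assert np.allclose(ca, [[11.639, 6.071, -5.147]], atol=1e-3)
        d = min_residue_distance(frame, 1083, 1084)
        brute = min(np.linalg.norm(p - q)
                    for p in frame.residue_coords(1083)
                    for q in frame.residue_coords(1084))
        assert d == pytest.approx(brute)

    def test_pair_catalog_yaml(self, tmp_path):
        from polphen.mdfeat import load_pair_list

        path = tmp_path / "pairs.yaml"
        path.write_text(
            "pairs:\n"
            "  - {name: K830-V1094, residues: [830, 1094], category: TL-BH}\n"
            "  - {name: H1085-GTP, residues: [1085, 2000], category: TL-GTP}\n"
        )
        pairs = load_pair_list(path)
        assert pairs == [("K830-V1094", 830, 1094, "TL-BH"),
                         ("H1085-GTP", 1085, 2000, "TL-GTP")]
        path.write_text(
            "pairs:\n"
            "  - {name: X, residues: [1, 2], category: bogus}\n")
        with pytest.raises(ValueError, match="category"):
            load_pair_list(path)


class TestSuperposeRMSD:
    def test_identity_zero(self, rng):
        X = rng.standard_normal((10, 3))
        assert superpose_rmsd(X, X) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        X = rng.standard_normal((12, 3))
        R = Rotation.random(random_state=3).as_matrix()
        moved = X @ R.T + np.array([5.0, -2.0, 1.0])
        assert superpose_rmsd(X, moved) == pytest.approx(0.0, abs=1e-8)

    def test_two_atom_closed_form(self):
        # atoms at +-L/2 on x; mobile copy stretched by d on one side:
        # optimal fit leaves each atom off by d/2 -> RMSD = d/2
        L, d = 4.0, 0.6
        ref = np.array([[-L / 2, 0, 0], [L / 2, 0, 0]])
        mob = np.array([[-L / 2, 0, 0], [L / 2 + d, 0, 0]])
        assert superpose_rmsd(ref, mob) == pytest.approx(d / 2)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(100):
            X = rng.standard_normal((8, 3))
            Y = rng.standard_normal((8, 3))
            Xc = X - X.mean(axis=0)
            Yc = Y - Y.mean(axis=0)
            rot, rssd = Rotation.align_vectors(Xc, Yc)
            oracle = rssd / np.sqrt(len(X))
            assert abs(superpose_rmsd(X, Y) - oracle) <= 1e-8

    def test_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            superpose_rmsd(rng.standard_normal((5, 3)), rng.standard_normal((6, 3)))
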