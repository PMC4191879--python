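"""Pose readers, torsions, conformer classification, RMSD, core restraint."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import horn_quaternion_rmsd, praxeolitic_dihedral
from terpchannel.structures import (
    AmbiguousConformerError,
    Atom,
    GeometryError,
    Pose,
    PoseFormatError,
    check_core_restraint,
    classify_conformer,
    dihedral,
    read_correspondence,
    read_pose,
    rmsd,
    write_mol2,
)

MOL2_3ATOM = """\
@<TRIPOS>MOLECULE
test
3 2 0 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
1 C1 0.000000 0.000000 0.000000 C.3 1 LIG 0.700000
2 C2 1.500000 0.000000 0.000000 C.3 1 LIG 0.100000
3 O1 2.100000 1.100000 0.000000 O.3 1 LIG -0.400000
@<TRIPOS>BOND
1 1 2 1
2 2 3 1
"""

SDF_3ATOM = """\
test
  synthetic

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
    1.5000    0.0000    0.0000 C   0  0
    2.1000    1.1000    0.0000 O   0  0
  1  2  1  0
  2  3  1  0
M  END
$$$$
"""

PDB_3ATOM = """\
HETATM    1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  C2  LIG A   1       1.500   0.000   0.000  1.00  0.00           C
HETATM    3  O1  LIG A   1       2.100   1.100   0.000  1.00  0.00           O
END
"""


class TestReaders:
    def test_mol2_coordinates_and_charges(self, tmp_path):
        p = tmp_path / "t.mol2"
        p.write_text(MOL2_3ATOM)
        pose = read_pose(p)
        assert [a.name for a in pose.atoms] == ["C1", "C2", "O1"]
        assert pose.atom("C1").charge == pytest.approx(0.7)
        assert pose.atom("O1").xyz == pytest.approx((2.1, 1.1, 0.0))
        assert pose.bonds == [(0, 1), (1, 2)]

    def test_same_molecule_mol2_and_sdf_match(self, tmp_path):
        p1 = tmp_path / "t.mol2"
        p1.write_text(MOL2_3ATOM)
        p2 = tmp_path / "t.sdf"
        p2.write_text(SDF_3ATOM)
        np.testing.assert_allclose(read_pose(p1).coords(), read_pose(p2).coords())

    def test_pdb_matches_mol2(self, tmp_path):
        p1 = tmp_path / "t.mol2"
        p1.write_text(MOL2_3ATOM)
        p2 = tmp_path / "t.pdb"
        p2.write_text(PDB_3ATOM)
        np.testing.assert_allclose(read_pose(p1).coords(), read_pose(p2).coords())

    def test_mol2_round_trip_exact(self, tmp_path):
        p = tmp_path / "t.mol2"
        p.write_text(MOL2_3ATOM)
        pose = read_pose(p)
        out = tmp_path / "rt.mol2"
        write_mol2(pose, out)
        back = read_pose(out)
        np.testing.assert_allclose(back.coords(), pose.coords())
        np.testing.assert_allclose(back.charges(), pose.charges())

    def test_malformed_mol2_reports_line(self, tmp_path):
        p = tmp_path / "bad.mol2"
        p.write_text("@<TRIPOS>MOLECULE\nx\n1 0\n\n\n@<TRIPOS>ATOM\n1 C1 a b c C.3\n")
        with pytest.raises(PoseFormatError, match=":7"):
            read_pose(p)

    def test_truncated_sdf_reports_line(self, tmp_path):
        p = tmp_path / "bad.sdf"
        p.write_text("t\n\n\n  5  0  0  0  0  0  0  0  0  0999 V2000\n")
        with pytest.raises(PoseFormatError, match="truncated"):
            read_pose(p)

    def test_duplicate_atom_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            Pose(atoms=[Atom("C1", "C", (0, 0, 0)), Atom("C1", "C", (1, 0, 0))])


def butane_like(phi_deg: float) -> list[np.ndarray]:
    """Four points with torsion exactly phi_deg.

    With p1=(−1,1,0), p2=origin, p3=(1,0,0) and p4=(2,cosφ,sinφ) the IUPAC
    torsion evaluates to exactly φ (derivable by hand from the atan2 form).
    """
    phi = np.radians(phi_deg)
    return [
        np.array([-1.0, 1.0, 0.0]),
        np.array([0.0, 0.0, 0.0]),
        np.array([1.0, 0.0, 0.0]),
        np.array([2.0, np.cos(phi), np.sin(phi)]),
    ]


class TestDihedral:
    def test_trans_planar_is_180(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)

    def test_cis_planar_is_0(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0)

    @pytest.mark.parametrize("phi", [-150.0, -60.0, -10.0, 10.0, 60.0, 120.0])
    def test_constructed_torsion_recovered(self, phi):
        assert dihedral(*butane_like(phi)) == pytest.approx(phi, abs=1e-9)

    def test_matches_independent_formula_on_random_quadruples(self):
        rng = np.random.default_rng(23)
        for _ in range(1000):
            pts = rng.normal(size=(4, 3)) * 3.0
            try:
                got = dihedral(*pts)
            except GeometryError:
                continue
            assert got == pytest.approx(praxeolitic_dihedral(*pts), abs=1e-9)

    def test_matches_biotite_reference(self):
        biotite_struct = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(29)
        for _ in range(200):
            pts = rng.normal(size=(4, 3)) * 3.0
            ref = float(np.degrees(
                biotite_struct.dihedral(pts[0], pts[1], pts[2], pts[3])
            ))
            # biotite evaluates in single precision
            assert dihedral(*pts) == pytest.approx(ref, abs=1e-3)

    def test_reversal_mirror_and_rigid_invariance(self):
        """Chain reversal preserves the signed torsion; mirror reflection
        negates it; rigid motion leaves it unchanged."""
        rng = np.random.default_rng(31)
        for _ in range(200):
            pts = rng.normal(size=(4, 3)) * 3.0
            try:
                fwd = dihedral(*pts)
            except GeometryError:
                continue
            assert dihedral(*pts[::-1]) == pytest.approx(fwd, abs=1e-9)
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            assert dihedral(*mirrored) == pytest.approx(-fwd, abs=1e-9) or (
                abs(fwd) == pytest.approx(180.0, abs=1e-9)
            )
            rot = Rotation.random(rng=rng)
            moved = rot.apply(pts) + rng.normal(size=3)
            assert dihedral(*moved) == pytest.approx(fwd, abs=1e-7)

    def test_degenerate_geometry_errors(self):
        with pytest.raises(GeometryError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
        with pytest.raises(GeometryError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


def i1_pose(phi_deg: float) -> Pose:
    pts = butane_like(phi_deg)
    names = ["C16", "C17", "C18", "H18"]
    return Pose(
        atoms=[
            Atom(n, n[0], tuple(p)) for n, p in zip(names, pts)
        ]
    )


IDENTITY_MAP = {k: k for k in ("C16", "C17", "C18", "H18")}


class TestClassifyConformer:
    def test_positive_torsion_is_a_like(self):
        assert classify_conformer(i1_pose(60.0), IDENTITY_MAP) == "A_like"

    def test_mirror_image_flips_to_bc_like(self):
        pose = i1_pose(60.0)
        mirrored = Pose(
            atoms=[
                Atom(a.name, a.element, (a.xyz[0], a.xyz[1], -a.xyz[2]), a.charge)
                for a in pose.atoms
            ]
        )
        assert classify_conformer(mirrored, IDENTITY_MAP) == "BC_like"

    def test_classification_equals_sign_of_dihedral_oracle(self):
        rng = np.random.default_rng(37)
        n_checked = 0
        for _ in range(300):
            pts = rng.normal(size=(4, 3)) * 3.0
            pose = Pose(
                atoms=[
                    Atom(n, n[0], tuple(p))
                    for n, p in zip(("C16", "C17", "C18", "H18"), pts)
                ]
            )
            try:
                phi = praxeolitic_dihedral(*pts)
                got = classify_conformer(pose, IDENTITY_MAP)
            except (GeometryError, AmbiguousConformerError):
                continue
            assert got == ("A_like" if phi > 0 else "BC_like")
            n_checked += 1
        assert n_checked > 250

    def test_near_zero_torsion_refused(self):
        with pytest.raises(AmbiguousConformerError):
            classify_conformer(i1_pose(0.4), IDENTITY_MAP)


def random_pose(rng, n=8, prefix="A"):
    return Pose(
        atoms=[
            Atom(f"{prefix}{k}", "C", tuple(rng.normal(size=3) * 4)) for k in range(n)
        ]
    )


class TestRmsd:
    def test_identical_poses_zero(self):
        rng = np.random.default_rng(41)
        pose = random_pose(rng)
        assert rmsd(pose, pose) == pytest.approx(0.0)
        assert rmsd(pose, pose, fit="kabsch") == pytest.approx(0.0, abs=1e-8)

    def test_rigid_shift(self):
        rng = np.random.default_rng(43)
        pose = random_pose(rng)
        shifted = pose.transformed(Rotation.identity(), np.array([1.0, 0.0, 0.0]))
        assert rmsd(pose, shifted) == pytest.approx(1.0)
        assert rmsd(pose, shifted, fit="kabsch") == pytest.approx(0.0, abs=1e-8)

    def test_kabsch_never_exceeds_in_place_and_matches_horn_oracle(self):
        rng = np.random.default_rng(47)
        for _ in range(200):
            a = random_pose(rng)
            b = random_pose(rng)
            corr = [(x.name, y.name) for x, y in zip(a.atoms, b.atoms)]
            in_place = rmsd(a, b, corr)
            kab = rmsd(a, b, corr, fit="kabsch")
            assert kab <= in_place + 1e-9
            oracle = horn_quaternion_rmsd(a.coords(), b.coords())
            assert kab == pytest.approx(oracle, abs=1e-8)

    def test_symmetry(self):
        rng = np.random.default_rng(53)
        a, b = random_pose(rng), random_pose(rng)
        corr = [(x.name, y.name) for x, y in zip(a.atoms, b.atoms)]
        rcorr = [(y, x) for x, y in corr]
        assert rmsd(a, b, corr) == pytest.approx(rmsd(b, a, rcorr))
        assert rmsd(a, b, corr, fit="kabsch") == pytest.approx(
            rmsd(b, a, rcorr, fit="kabsch"), abs=1e-8
        )

    def test_empty_correspondence_errors(self):
        rng = np.random.default_rng(59)
        with pytest.raises(ValueError, match="empty"):
            rmsd(random_pose(rng), random_pose(rng), [])


class TestCoreRestraint:
    def test_small_deviation_passes(self):
        pose = Pose(atoms=[Atom("C1", "C", (0.42, 0.0, 0.0))])
        assert check_core_restraint(pose, {"C1": (0.0, 0.0, 0.0)})

    def test_large_deviation_fails(self):
        pose = Pose(atoms=[Atom("C1", "C", (1.5, 0.0, 0.0))])
        assert not check_core_restraint(pose, {"C1": (0.0, 0.0, 0.0)})

    def test_boundary_is_inclusive(self):
        pose = Pose(atoms=[Atom("C1", "C", (1.0, 0.0, 0.0))])
        assert check_core_restraint(pose, {"C1": (0.0, 0.0, 0.0)}, tolerance=1.0)


def test_read_correspondence(tmp_path):
    p = tmp_path / "core.txt"
    p.write_text("# core mapping\nC1 C1\nC2 C2a  # shifted name\n\n")
    assert read_correspondence(p) == [("C1", "C1"), ("C2", "C2a")]
    bad = tmp_path / "bad.txt"
    bad.write_text("C1 C2 C3\n")
    with pytest.raises(ValueError, match=":1"):
        read_correspondence(bad)
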