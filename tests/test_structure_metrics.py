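import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from gepi_screen.structure_metrics import (
    DescriptorError,
    GeometryError,
    StructureParseError,
    Trajectory,
    backbone_dihedrals,
    dihedral,
    improper_phi,
    improper_phi_series,
    parse_structure,
    percent_helicity,
    polar_side_chain_atom,
    same_face_fraction,
    wrap_angle,
    write_pdb,
)
from gepi_screen.synthetic_data import (
    coil_trajectory,
    extended_strand,
    ideal_helix,
    noisy_helix_trajectory,
)

from conftest import DBAD1

CIS = [(1, 0, 0), (0, 0, 0), (0, 1, 0), (1, 1, 0)]


def analytic_helix_phi(s: int) -> float:
    """Closed-form Phi for residues s apart on an ideal alpha-helix cylinder
    lattice: an oracle independent of the coordinate builder.

    The four points are constructed directly in cylindrical coordinates.
    Cylinder parameters are the measured geometry of an ideal (-57, -47)
    helix of L-amino acids: CA radius 2.27 A, rise 1.56 A/residue, twist
    -98.9 deg/residue (sign in the torsion convention used throughout), and
    side chains tilted 30 deg toward the N-terminus with their azimuth
    trailing the CA radial direction by 46.2 deg.
    """
    radius, rise, twist = 2.27, 1.56, -98.9
    tilt = math.radians(-30.0)
    azi = math.radians(-46.2)
    pts = {}
    for k in (0, s):
        ang = math.radians(twist * k)
        ca = np.array([radius * math.cos(ang), radius * math.sin(ang), rise * k])
        sang = ang + azi
        side = np.array([math.cos(sang), math.sin(sang), 0.0]) * math.cos(tilt) + np.array(
            [0.0, 0.0, 1.0]
        ) * math.sin(tilt)
        pts[k] = (ca, ca + 2.42 * side)
    return dihedral(pts[0][1], pts[0][0], pts[s][0], pts[s][1])


class TestDihedral:
    def test_planar_cis_zero(self):
        assert dihedral(*CIS) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_180(self):
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (-1, 1, 0)) == pytest.approx(180.0)

    def test_known_rotation_angle(self):
        # rotate the cis endpoint by 73 deg about the p3->p2 direction
        # (positive torsion = clockwise viewed from p2 toward p3)
        rot = Rotation.from_rotvec(np.deg2rad(73.0) * np.array([0.0, -1.0, 0.0]))
        p4 = rot.apply([1, 1, 0])
        assert dihedral(CIS[0], CIS[1], CIS[2], p4) == pytest.approx(73.0, abs=1e-9)

    def test_collinear_rejected(self):
        with pytest.raises(GeometryError):
            dihedral((2, 0, 0), (1, 0, 0), (0, 0, 0), (0, 1, 0))

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3))
        try:
            ref = dihedral(*pts)
        except GeometryError:
            return
        rot = Rotation.random(rng=np.random.default_rng(seed))
        shift = rng.normal(size=3) * 10
        moved = rot.apply(pts) + shift
        assert dihedral(*moved) == pytest.approx(ref, abs=1e-8)

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000))
    def test_reversal_symmetry(self, seed):
        rng = np.random.default_rng(seed + 1)
        p = rng.normal(size=(4, 3))
        try:
            a = dihedral(*p)
        except GeometryError:
            return
        assert dihedral(p[3], p[2], p[1], p[0]) == pytest.approx(a, abs=1e-10)


class TestPolarSideChainAtom:
    @pytest.mark.parametrize(
        "res,atom", [("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG")]
    )
    def test_nomenclature(self, res, atom):
        assert polar_side_chain_atom(res) == atom

    def test_no_polar_atom(self):
        assert polar_side_chain_atom("ALA") is None


class TestImproperPhi:
    def test_same_residue_rejected(self, poly_ser_helix):
        with pytest.raises(DescriptorError):
            improper_phi(poly_ser_helix, 3, 3)

    def test_nonpolar_residue_rejected(self):
        conf = ideal_helix("SASAS")
        with pytest.raises(DescriptorError):
            improper_phi(conf, 1, 2)

    def test_pair_symmetry(self, poly_ser_helix):
        assert improper_phi(poly_ser_helix, 2, 9) == improper_phi(poly_ser_helix, 9, 2)

    def test_spacing_seven_same_face(self, poly_ser_helix):
        assert abs(improper_phi(poly_ser_helix, 1, 8)) < 90.0

    def test_spacing_two_opposite_face(self, poly_ser_helix):
        assert abs(improper_phi(poly_ser_helix, 1, 3)) > 90.0

    @pytest.mark.parametrize("s", range(1, 11))
    def test_matches_analytic_cylinder_model(self, poly_ser_helix, s):
        """The atomic builder agrees with the independent closed-form
        cylinder-lattice construction of Phi_ij."""
        measured = improper_phi(poly_ser_helix, 2, 2 + s)
        predicted = analytic_helix_phi(s)
        assert abs(wrap_angle(measured - predicted)) < 10.0

    @pytest.mark.parametrize("s", range(3, 11))
    def test_wheel_offset_at_larger_spacings(self, poly_ser_helix, s):
        """As spacing grows the CA-CA torsion axis aligns with the helix axis
        and Phi_ij approaches the helical-wheel offset wrap(s x 100 deg).
        30 deg is the empirical envelope of the residual axis-tilt distortion
        at these spacings; at s <= 2 the distortion is much larger (see the
        analytic-cylinder test, which is exact at all spacings)."""
        measured = improper_phi(poly_ser_helix, 2, 2 + s)
        assert abs(wrap_angle(measured - wrap_angle(s * 100.0))) < 30.0

    def test_series_records_atom_quadruple(self, poly_ser_helix):
        traj = Trajectory(frames=[poly_ser_helix])
        series = improper_phi_series(traj, 1, 8)
        assert series.atoms_used == ("OG:1", "CA:1", "CA:8", "OG:8")
        assert all(-180 < a <= 180 for a in series.phi_ij)


class TestSameFaceFraction:
    def test_ideal_helix_spacing_seven(self):
        traj = noisy_helix_trajectory("S" * 15, 5, 0.0, seed=1)
        assert same_face_fraction(traj, 1, 8) == 1.0

    def test_ideal_helix_spacing_two(self):
        traj = noisy_helix_trajectory("S" * 15, 5, 0.0, seed=1)
        assert same_face_fraction(traj, 1, 3) == 0.0

    def test_full_threshold_always_one(self, dbad1_coil):
        assert same_face_fraction(dbad1_coil, 1, 8, threshold=180.0) == 1.0

    def test_coil_near_uniform(self, dbad1_coil):
        # random-coil null: |Phi| <= 90 covers half the circle
        frac = same_face_fraction(dbad1_coil, 1, 8)
        assert 0.4 <= frac <= 0.6


class TestBackboneDihedrals:
    def test_ideal_helix_by_construction(self):
        angles = backbone_dihedrals(ideal_helix("A" * 10))
        for idx in range(2, 10):
            phi, psi = angles[idx]
            assert phi == pytest.approx(-57.0, abs=0.5)
            assert psi == pytest.approx(-47.0, abs=0.5)
        assert angles[1][0] is None and angles[10][1] is None

    def test_extended_strand_by_construction(self):
        angles = backbone_dihedrals(extended_strand("A" * 8))
        for idx in range(2, 8):
            assert abs(angles[idx][0]) == pytest.approx(180.0, abs=0.5)
            assert abs(angles[idx][1]) == pytest.approx(180.0, abs=0.5)


class TestPercentHelicity:
    def test_ideal_helix_is_100(self):
        traj = noisy_helix_trajectory("A" * 15, 3, 0.0, seed=0)
        assert percent_helicity(traj).percent_helicity == pytest.approx(100.0)

    def test_extended_strand_is_0(self):
        traj = Trajectory(frames=[extended_strand("A" * 15)])
        assert percent_helicity(traj).percent_helicity == 0.0

    def test_coil_regression_below_10(self, dbad1_coil):
        assert percent_helicity(dbad1_coil).percent_helicity < 10.0

    def test_monotone_in_noise(self):
        values = [
            percent_helicity(
                noisy_helix_trajectory(DBAD1, 30, noise, seed=5)
            ).percent_helicity
            for noise in (0.0, 10.0, 30.0, 60.0)
        ]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert values[0] == pytest.approx(100.0)


class TestStructureIO:
    def test_single_model_round_trip(self, tmp_path):
        conf = ideal_helix(DBAD1)
        path = tmp_path / "helix.pdb"
        write_pdb(conf, path)
        traj = parse_structure(path)
        assert traj.n_frames == 1
        assert traj.frames[0].n_residues == 15
        np.testing.assert_allclose(
            traj.frames[0].coord(8, "CA"), conf.coord(8, "CA"), atol=1e-3
        )

    def test_multi_model_round_trip(self, tmp_path):
        traj = noisy_helix_trajectory("STS", 10, 5.0, seed=9)
        path = tmp_path / "traj.pdb"
        write_pdb(traj, path)
        assert parse_structure(path).n_frames == 10

    def test_missing_backbone_atom_rejected(self, tmp_path):
        conf = ideal_helix("SSS")
        conf.atoms = [a for a in conf.atoms if not (a.residue_index == 2 and a.atom_name == "CA")]
        path = tmp_path / "broken.pdb"
        lines = []
        from gepi_screen.structure_metrics import _format_atom_line

        for i, a in enumerate(conf.atoms, 1):
            lines.append(_format_atom_line(i, a))
        path.write_text("\n".join(lines) + "\nEND\n")
        with pytest.raises(StructureParseError, match="residue 2"):
            parse_structure(path)
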