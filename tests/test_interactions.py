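"""H-bond detection thresholds, Coulomb energy, and the canonical pattern."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cannmotif.core import Atom, GeometryError
from cannmotif.interactions import (
    classify_energy,
    detect_hbond,
    hbond_energy,
    is_canonical_pattern,
    map_anion_contacts,
)


def _atoms_at(d_ho: float, angle: float, donor_kind: str = "N"):
    """Donor X at origin, H on +x, acceptor O at the requested geometry."""
    heavy_name = "N" if donor_kind == "N" else "CA"
    x = Atom(1, heavy_name, 3, "LYS", heavy_name[0], np.zeros(3))
    h = Atom(2, "H", 3, "LYS", "H", np.array([1.01, 0.0, 0.0]))
    theta = math.radians(180.0 - angle)  # X-H...O angle
    o = h.xyz + d_ho * np.array([math.cos(theta), math.sin(theta), 0.0])
    acceptor = Atom(3, "O1", 99, "SO4", "O", o)
    return x, h, acceptor


class TestDetectHBond:
    def test_docked_amide_geometry_accepted(self):
        """The reported N(+1) geometry (1.71 A, 160.03 deg) is a contact."""
        x, h, o = _atoms_at(1.71, 160.03, "N")
        c = detect_hbond(x, h, o, "N")
        assert c is not None
        assert c.d_ho == pytest.approx(1.71, abs=1e-6)
        assert c.angle_xho == pytest.approx(160.03, abs=1e-6)

    @pytest.mark.parametrize(
        "donor_kind,d,angle,accepted",
        [
            ("N", 2.7, 160.0, True),     # amide cutoff inclusive
            ("N", 2.701, 160.0, False),
            ("Calpha", 3.0, 120.0, True),  # alpha-carbon cutoff inclusive
            ("Calpha", 3.5, 120.0, False),
            ("N", 1.9, 90.0, True),      # angle threshold inclusive
            ("N", 1.9, 89.9, False),
        ],
    )
    def test_threshold_boundaries(self, donor_kind, d, angle, accepted):
        x, h, o = _atoms_at(d, angle, donor_kind)
        c = detect_hbond(x, h, o, donor_kind)
        assert (c is not None) is accepted

    def test_unbonded_hydrogen_is_precondition_error(self):
        x, h, o = _atoms_at(1.9, 160.0)
        h.xyz = h.xyz + np.array([1.0, 0.0, 0.0])  # 2.01 A from the donor
        with pytest.raises(ValueError, match="not covalently bonded"):
            detect_hbond(x, h, o, "N")

    def test_rigid_motion_invariance(self):
        """Detection geometry is unchanged by any rotation + translation."""
        rng = np.random.default_rng(11)
        x, h, o = _atoms_at(2.1, 140.0, "N")
        base = detect_hbond(x, h, o, "N")
        for _ in range(10):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(scale=20.0, size=3)
            moved = []
            for a in (x, h, o):
                b = Atom(a.serial, a.name, a.residue_index, a.residue_code, a.element, R @ a.xyz + t)
                moved.append(b)
            c = detect_hbond(moved[0], moved[1], moved[2], "N")
            assert c is not None
            assert c.d_ho == pytest.approx(base.d_ho, abs=1e-9)
            assert c.angle_xho == pytest.approx(base.angle_xho, abs=1e-7)


class TestHBondEnergy:
    def test_matches_hand_evaluated_four_term_sum(self):
        """Collinear S=O...H-N geometry scores the frozen arithmetic value.

        With r_OH = 1.9, r_SH = 3.39, r_ON = 2.91, r_SN = 4.40 the four-term
        sum is 332*(0.48/3.39 - 0.8/4.40 - 0.27/1.9 + 0.45/2.91) = -9.1935.
        """
        s = np.array([0.0, 0.0, 0.0])
        o = np.array([1.49, 0.0, 0.0])
        h = np.array([3.39, 0.0, 0.0])
        n = np.array([4.40, 0.0, 0.0])
        e = hbond_energy("N", s, o, h, n)
        assert e == pytest.approx(-9.193528, abs=1e-4)

    def test_calpha_donor_uses_alpha_charges(self):
        s = np.array([0.0, 0.0, 0.0])
        o = np.array([1.49, 0.0, 0.0])
        h = np.array([3.99, 0.0, 0.0])
        ca = np.array([5.08, 0.0, 0.0])
        expected = 332.0 * (
            1.6 * 0.06 / 3.99
            + 1.6 * (-0.1) / 5.08
            + (-0.9) * 0.06 / 2.5
            + (-0.9) * (-0.1) / 3.59
        )
        assert hbond_energy("Calpha", s, o, h, ca) == pytest.approx(expected, abs=1e-9)

    def test_inverse_distance_homogeneity(self):
        s, o = np.zeros(3), np.array([1.49, 0.0, 0.0])
        h, n = np.array([3.39, 0.0, 0.0]), np.array([4.40, 0.0, 0.0])
        e1 = hbond_energy("N", s, o, h, n)
        e2 = hbond_energy("N", 2 * s, 2 * o, 2 * h, 2 * n)
        assert e2 == pytest.approx(e1 / 2.0, rel=1e-12)

    def test_vanishes_at_infinite_separation(self):
        s, o = np.zeros(3), np.array([1.49, 0.0, 0.0])
        h = np.array([1e9, 0.0, 0.0])
        n = np.array([1e9 + 1.01, 0.0, 0.0])
        assert abs(hbond_energy("N", s, o, h, n)) < 1e-5

    def test_coincident_acceptor_and_hydrogen_raise(self):
        p = np.zeros(3)
        with pytest.raises(GeometryError):
            hbond_energy("N", np.array([1.49, 0.0, 0.0]), p, p, np.ones(3))


class TestClassifyEnergy:
    @pytest.mark.parametrize(
        "energy,label",
        [
            (-9.2, "strong"),
            (-1.0, "strong"),   # boundary: non-strict "<=" goes to strong
            (-0.999, "weak"),
            (-0.7, "weak"),
            (-0.5, "weak"),     # boundary: -0.5 still counts as weak
            (-0.499, "none"),
            (0.0, "none"),
            (5.0, "none"),
        ],
    )
    def test_boundaries(self, energy, label):
        assert classify_energy(energy) == label

    def test_partitions_the_real_line(self):
        rng = np.random.default_rng(3)
        for e in rng.normal(scale=3.0, size=500):
            assert classify_energy(float(e)) in ("strong", "weak", "none")

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_energy(float("nan"))


class TestCanonicalPattern:
    MOTIF = (2, 3, 4)
    DONORS = ("Calpha:2", "N:3", "N:4")

    def _reference_predicate(self, oxygen_map):
        """Direct restatement of the pattern definition, kept independent."""
        engaged = {o: s for o, s in oxygen_map.items() if s}
        if len(engaged) != 2:
            return False
        sets = list(engaged.values())
        for bridge_set, lone_set in (sets, sets[::-1]):
            if (
                "Calpha:2" in bridge_set
                and "N:3" in bridge_set
                and lone_set == {"N:4"}
            ):
                return True
        return False

    def test_exhaustive_enumeration_of_contact_sets(self):
        """Predicate agrees with the definition over all 4096 donor subsets."""
        subsets = list(
            frozenset(c)
            for r in range(4)
            for c in itertools.combinations(self.DONORS, r)
        )
        count_true = 0
        for assignment in itertools.product(subsets, repeat=4):
            oxygen_map = {
                f"O{k + 1}": set(s) for k, s in enumerate(assignment) if s
            }
            expected = self._reference_predicate(
                {f"O{k + 1}": set(s) for k, s in enumerate(assignment)}
            )
            got = is_canonical_pattern(oxygen_map, self.MOTIF)
            assert got == expected, oxygen_map
            count_true += got
        assert count_true > 0

    def test_three_engaged_oxygens_never_canonical(self):
        oxygen_map = {
            "O1": {"Calpha:2", "N:3"},
            "O2": {"N:4"},
            "O3": {"N:4"},
        }
        assert not is_canonical_pattern(oxygen_map, self.MOTIF)


class TestMapAnionContacts:
    def test_generated_pose_is_canonical(self, canonical_pose, motif):
        structure, anion, _ = canonical_pose
        inter = map_anion_contacts(structure, anion, motif)
        assert inter.canonical
        assert inter.n_interacting_oxygens == 2
        donors = {c.donor_id for c in inter.contacts}
        assert donors == {"Calpha:2", "N:3", "N:4"}

    def test_distant_anion_gives_no_contacts(self, canonical_pose, motif):
        structure, anion, _ = canonical_pose
        far = anion.transformed(np.eye(3), np.array([20.0, 0.0, 0.0]))
        inter = map_anion_contacts(structure, far, motif)
        assert inter.contacts == []
        assert not inter.canonical

    def test_close_amide_contacts_score_below_weak_threshold(
        self, canonical_pose, small_ensemble, motif
    ):
        """Geometric N-H contacts at d <= 2.1 A and angle >= 150 deg are at
        least weak H-bonds under the default charges."""
        checked = 0
        for structure, anion in small_ensemble:
            inter = map_anion_contacts(structure, anion, motif)
            for c in inter.contacts:
                if c.donor_kind == "N" and c.d_ho <= 2.1 and c.angle_xho >= 150:
                    assert c.energy <= -0.5
                    checked += 1
        assert checked > 10

    def test_missing_amide_hydrogen_is_instructive_error(
        self, canonical_pose, motif
    ):
        structure, anion, _ = canonical_pose
        stripped = structure.copy()
        stripped.atoms = [
            a for a in stripped.atoms if not (a.residue_index == 3 and a.name == "H")
        ]
        with pytest.raises(ValueError, match="hydrogen"):
            map_anion_contacts(stripped, anion, motif)

    def test_rigid_motion_preserves_interaction(self, canonical_pose, motif):
        structure, anion, _ = canonical_pose
        R = Rotation.from_euler("xyz", [30, -60, 110], degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 8.0])
        inter0 = map_anion_contacts(structure, anion, motif)
        inter1 = map_anion_contacts(
            structure.transformed(R, t), anion.transformed(R, t), motif
        )
        assert inter1.canonical == inter0.canonical
        assert len(inter1.contacts) == len(inter0.contacts)
        for c0, c1 in zip(inter0.contacts, inter1.contacts):
            assert c1.d_ho == pytest.approx(c0.d_ho, abs=1e-9)
            assert c1.angle_xho == pytest.approx(c0.angle_xho, abs=1e-6)
            assert c1.energy == pytest.approx(c0.energy, abs=1e-9)
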