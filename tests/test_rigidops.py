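"""Two-body rigid manipulations: examples, rigidity, and oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from structmanip.geometry import GeometryError, Plane, mass_center
from structmanip.rigidops import (min_interunit_distance, rotate_about,
                                  separate, spin, translate_perpendicular)
from tests.conftest import make_random_unit


def pairwise_distances(unit):
    pos = unit.positions
    return np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)


@pytest.fixture
def pair(random_unit):
    fixed = random_unit(seed=100, center=(0, 0, 0), label="fixed")
    mobile = random_unit(seed=101, center=(30, 0, 0), label="mobile")
    return fixed, mobile


class TestSeparate:
    def test_moves_center_along_the_line(self, random_unit):
        fixed = random_unit(seed=1, n_atoms=20, center=(0, 0, 0), spread=0.5)
        mobile = random_unit(seed=2, n_atoms=20, center=(10, 0, 0), spread=0.5)
        # pin the centers exactly
        fixed = fixed.with_positions(
            fixed.positions - mass_center(fixed))
        mobile = mobile.with_positions(
            mobile.positions - mass_center(mobile) + [10, 0, 0])
        result = separate(fixed, mobile, 5.0)
        assert np.allclose(mass_center(result.unit), [15, 0, 0], atol=1e-9)
        assert np.allclose(result.displacement_of_center, [5, 0, 0])

    def test_zero_distance_is_identity(self, pair):
        fixed, mobile = pair
        result = separate(fixed, mobile, 0.0)
        assert np.abs(result.unit.positions - mobile.positions).max() < 1e-12

    def test_negative_distance_closes_the_gap(self, pair):
        fixed, mobile = pair
        d0 = np.linalg.norm(mass_center(mobile) - mass_center(fixed))
        result = separate(fixed, mobile, -3.0)
        d1 = np.linalg.norm(mass_center(result.unit) - mass_center(fixed))
        assert d1 == pytest.approx(d0 - 3.0, abs=1e-9)

    def test_round_trip(self, pair):
        fixed, mobile = pair
        back = separate(fixed, separate(fixed, mobile, 7.3).unit, -7.3).unit
        assert np.abs(back.positions - mobile.positions).max() < 1e-9

    def test_coincident_centers_error(self, random_unit):
        u = random_unit(seed=3)
        with pytest.raises(GeometryError, match="coincide"):
            separate(u, u.copy(), 5.0)


class TestRotateAbout:
    def test_quarter_turn_moves_center(self, random_unit):
        fixed = random_unit(seed=4, n_atoms=20, spread=0.5)
        fixed = fixed.with_positions(fixed.positions - mass_center(fixed))
        mobile = random_unit(seed=5, n_atoms=20, center=(10, 0, 0), spread=0.5)
        mobile = mobile.with_positions(
            mobile.positions - mass_center(mobile) + [10, 0, 0])
        result = rotate_about(fixed, mobile, Plane.XY, 90.0)
        assert np.allclose(mass_center(result.unit), [0, 10, 0], atol=1e-9)

    def test_full_turn_and_inverse_composition_are_identity(self, pair):
        fixed, mobile = pair
        full = rotate_about(fixed, mobile, Plane.XY, 360.0).unit
        assert np.abs(full.positions - mobile.positions).max() < 1e-6
        once = rotate_about(fixed, mobile, Plane.XZ, 25.0).unit
        back = rotate_about(fixed, once, Plane.XZ, -25.0).unit
        assert np.abs(back.positions - mobile.positions).max() < 1e-6

    def test_preserves_center_separation(self, pair):
        fixed, mobile = pair
        d0 = np.linalg.norm(mass_center(mobile) - mass_center(fixed))
        for angle in (13.0, -77.0, 191.0):
            u = rotate_about(fixed, mobile, Plane.YZ, angle).unit
            d1 = np.linalg.norm(mass_center(u) - mass_center(fixed))
            assert d1 == pytest.approx(d0, abs=1e-9)

    def test_out_of_plane_coordinate_untouched(self, pair):
        fixed, mobile = pair
        u = rotate_about(fixed, mobile, Plane.XY, 37.0).unit
        assert np.array_equal(u.positions[:, 2], mobile.positions[:, 2])

    @settings(derandomize=True, max_examples=25)
    @given(angle=st.floats(-360, 360), plane=st.sampled_from(list(Plane)),
           seed=st.integers(0, 10))
    def test_agrees_with_quaternion_oracle(self, angle, plane, seed):
        """Independent oracle: scipy quaternion rotation about C_fixed."""
        fixed = make_random_unit(seed=200 + seed, n_atoms=20)
        mobile = make_random_unit(seed=300 + seed, n_atoms=20,
                                  center=(25, 10, -5))
        ours = rotate_about(fixed, mobile, plane, angle).unit.positions
        c = mass_center(fixed)
        rot = Rotation.from_euler(plane.axis, angle, degrees=True)
        oracle = rot.apply(mobile.positions - c) + c
        assert np.abs(ours - oracle).max() < 1e-9


class TestSpin:
    def test_double_half_turn_is_identity(self, pair):
        _, mobile = pair
        twice = spin(spin(mobile, Plane.XY, 180.0).unit, Plane.XY, 180.0).unit
        assert np.abs(twice.positions - mobile.positions).max() < 1e-6

    def test_mass_center_is_a_fixed_point(self, pair):
        _, mobile = pair
        before = mass_center(mobile)
        after = mass_center(spin(mobile, Plane.YZ, 123.0).unit)
        assert np.abs(after - before).max() < 1e-9

    def test_xy_spin_preserves_z_bitwise(self, random_unit):
        mobile = random_unit(seed=6, n_atoms=4, center=(10, 0, 0))
        mobile.atoms[0].position[2] = 1.0
        mobile.atoms[1].position[2] = 2.5
        result = spin(mobile, Plane.XY, 33.7).unit
        assert np.array_equal(result.positions[:, 2], mobile.positions[:, 2])


class TestTranslatePerpendicular:
    def test_hand_rotated_displacement(self, random_unit):
        fixed = random_unit(seed=7, n_atoms=20, spread=0.5)
        fixed = fixed.with_positions(fixed.positions - mass_center(fixed))
        mobile = random_unit(seed=8, n_atoms=20, center=(10, 0, 0), spread=0.5)
        mobile = mobile.with_positions(
            mobile.positions - mass_center(mobile) + [10, 0, 0])
        result = translate_perpendicular(fixed, mobile, Plane.XY, 5.0,
                                         sense=90)
        assert np.allclose(result.displacement_of_center, [0, 5, 0],
                           atol=1e-12)
        down = translate_perpendicular(fixed, mobile, Plane.XY, 5.0, sense=-90)
        assert np.allclose(down.displacement_of_center, [0, -5, 0],
                           atol=1e-12)

    def test_zero_distance_is_identity(self, pair):
        fixed, mobile = pair
        u = translate_perpendicular(fixed, mobile, Plane.XY, 0.0).unit
        assert np.abs(u.positions - mobile.positions).max() < 1e-12

    def test_displacement_orthogonal_to_inplane_center_line(self, pair):
        fixed, mobile = pair
        m_vec = mass_center(mobile) - mass_center(fixed)
        for plane in Plane:
            result = translate_perpendicular(fixed, mobile, plane, 8.0)
            m_inplane = m_vec.copy()
            m_inplane[plane.axis_index] = 0.0
            assert abs(result.displacement_of_center @ m_inplane) < 1e-9

    def test_center_line_perpendicular_to_plane_errors(self, random_unit):
        fixed = random_unit(seed=9, n_atoms=10, spread=0.5)
        fixed = fixed.with_positions(fixed.positions - mass_center(fixed))
        mobile = random_unit(seed=10, n_atoms=10, spread=0.5)
        mobile = mobile.with_positions(
            mobile.positions - mass_center(mobile) + [0, 0, 20])
        with pytest.raises(GeometryError, match="no component"):
            translate_perpendicular(fixed, mobile, Plane.XY, 5.0)


class TestMinInterunitDistance:
    def test_three_four_five(self, random_unit):
        a = random_unit(seed=11, n_atoms=1)
        a.atoms[0].position[:] = [0, 0, 0]
        b = random_unit(seed=12, n_atoms=1)
        b.atoms[0].position[:] = [3, 4, 0]
        assert min_interunit_distance(a, b) == pytest.approx(5.0)

    def test_overlapping_units_touch(self, random_unit):
        a = random_unit(seed=13, n_atoms=30)
        assert min_interunit_distance(a, a.copy()) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_double_loop(self, seed, random_unit):
        a = random_unit(seed=400 + seed, n_atoms=200)
        b = random_unit(seed=500 + seed, n_atoms=200, center=(12, 3, -4))
        brute = min(float(np.linalg.norm(x.position - y.position))
                    for x in a.atoms for y in b.atoms)
        assert min_interunit_distance(a, b) == brute


@pytest.mark.parametrize("seed", range(20))
def test_all_operations_are_rigid(seed, random_unit):
    """Every intra-unit pairwise distance preserved to 1e-6 A."""
    fixed = random_unit(seed=1000 + seed, n_atoms=100)
    mobile = random_unit(seed=2000 + seed, n_atoms=100, center=(40, -10, 5))
    ref = pairwise_distances(mobile)
    results = [
        separate(fixed, mobile, 7.7),
        rotate_about(fixed, mobile, Plane.XZ, 33.0),
        spin(mobile, Plane.YZ, -141.0),
        translate_perpendicular(fixed, mobile, Plane.XY, 9.5),
    ]
    for res in results:
        assert len(res.unit) == len(mobile)
        assert np.abs(pairwise_distances(res.unit) - ref).max() < 1e-6
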