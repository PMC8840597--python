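"""Geometric detectors: worked examples, boundary rules, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from opidyn.errors import ConfigurationError
from opidyn.interactions import (
    GeometricCriteria,
    InteractionType,
    detect_cation_pi,
    detect_clash,
    detect_hbond,
    detect_hydrophobic,
    detect_ionic,
    detect_water_mediated,
)

from . import oracles


def frame_of(*points):
    return np.asarray(points, dtype=float)


def hexagon(center, radius=1.39, tilt=0.0):
    pts = []
    for k in range(6):
        a = np.pi * k / 3
        pts.append([center[0] + radius * np.cos(a),
                    center[1] + radius * np.sin(a),
                    center[2] + tilt * np.sin(a)])
    return pts


class TestIonic:
    @pytest.mark.parametrize("d,expected", [(3.0, True), (4.5, True), (10.0, False)])
    def test_cutoff_with_inclusive_boundary(self, criteria, d, expected):
        frame = frame_of([0, 0, 0], [0, 0, d])
        event = detect_ionic(frame, [0], [1], criteria)
        if expected:
            assert event is not None and event.distance == pytest.approx(d)
        else:
            assert event is None

    def test_min_over_group_atoms(self, criteria):
        frame = frame_of([0, 0, 0], [0, 0, 9.0], [0, 0, 4.0])
        event = detect_ionic(frame, [0], [1, 2], criteria)
        assert event.distance == pytest.approx(4.0)

    def test_empty_group_rejected(self, criteria):
        with pytest.raises(ValueError):
            detect_ionic(frame_of([0, 0, 0]), [0], [], criteria)


class TestHBond:
    def test_good_distance_and_angle(self, criteria):
        # root -- donor ... acceptor at 160 degrees
        donor = np.array([0.0, 0.0, 0.0])
        root = np.array([-1.5, 0.0, 0.0])
        ang = np.radians(160.0)
        acceptor = donor + 2.9 * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0])
        frame = frame_of(root, donor, acceptor)
        event = detect_hbond(frame, [1], [2], criteria, donor_root_idx=[0])
        assert event is not None
        assert event.distance == pytest.approx(2.9)
        assert event.angle == pytest.approx(160.0, abs=1e-6)

    def test_angle_failure(self, criteria):
        frame = frame_of([-1.5, 0, 0], [0, 0, 0], [0, 2.9, 0])  # 90 degrees
        assert detect_hbond(frame, [1], [2], criteria, donor_root_idx=[0]) is None

    def test_distance_failure(self, criteria):
        frame = frame_of([-1.5, 0, 0], [0, 0, 0], [4.5, 0, 0])
        assert detect_hbond(frame, [1], [2], criteria, donor_root_idx=[0]) is None

    def test_strict_mode_needs_hydrogens(self, criteria):
        frame = frame_of([0, 0, 0], [2.9, 0, 0])
        with pytest.raises(ValueError):
            detect_hbond(frame, [0], [1], criteria, strict=True)


class TestWaterMediated:
    def test_bridge_through_single_water(self, criteria):
        frame = frame_of([0, 0, 0], [2.8, 0, 0], [5.6, 0, 0])
        event = detect_water_mediated(frame, [0], [2], {7: np.array([1])}, criteria)
        assert event is not None and event.water_id == 7
        assert event.itype is InteractionType.WATER_MEDIATED

    def test_no_waters_no_event(self, criteria):
        frame = frame_of([0, 0, 0], [5.6, 0, 0])
        assert detect_water_mediated(frame, [0], [1], {}, criteria) is None

    def test_one_long_leg_fails(self, criteria):
        frame = frame_of([0, 0, 0], [5.0, 0, 0], [7.8, 0, 0])
        assert detect_water_mediated(frame, [0], [2], {1: np.array([1])},
                                     criteria) is None


class TestHydrophobic:
    def test_contact_and_miss(self, criteria):
        frame = frame_of([0, 0, 0], [4.0, 0, 0])
        assert detect_hydrophobic(frame, [0], [1], criteria) is not None
        frame = frame_of([0, 0, 0], [6.0, 0, 0])
        assert detect_hydrophobic(frame, [0], [1], criteria) is None

    def test_polar_only_group_yields_nothing(self, criteria):
        frame = frame_of([0, 0, 0], [3.0, 0, 0])
        elements = np.array(["N", "C"])
        assert detect_hydrophobic(frame, [0], [1], criteria,
                                  elements=elements) is None


class TestCationPi:
    def test_on_axis_hit_in_plane_miss(self, criteria):
        ring = hexagon([0, 0, 0])
        frame = np.asarray(ring + [[0, 0, 4.0], [4.0, 0, 0], [0, 0, 10.0]])
        ring_idx = list(range(6))
        assert detect_cation_pi(frame, [6], ring_idx, criteria) is not None
        assert detect_cation_pi(frame, [7], ring_idx, criteria) is None  # 90 deg
        assert detect_cation_pi(frame, [8], ring_idx, criteria) is None  # far

    def test_nonplanar_ring_rejected(self, criteria):
        ring = hexagon([0, 0, 0])
        for k in range(6):   # chair-like distortion, genuinely non-planar
            ring[k][2] += 1.5 if k % 2 else -1.5
        frame = np.asarray(ring + [[0, 0, 4.0]])
        with pytest.raises(ValueError, match="plane"):
            detect_cation_pi(frame, [6], list(range(6)), criteria)


class TestClash:
    def test_overlap_and_clearance(self, criteria):
        frame = frame_of([0, 0, 0], [1.0, 0, 0])
        elements = np.array(["C", "C"])
        events = detect_clash(frame, [0], [1], elements, criteria)
        assert len(events) == 1 and events[0].itype is InteractionType.CLASH
        frame = frame_of([0, 0, 0], [3.5, 0, 0])
        assert detect_clash(frame, [0], [1], elements, criteria) == []

    def test_unknown_element_is_config_error(self, criteria):
        frame = frame_of([0, 0, 0], [1.0, 0, 0])
        with pytest.raises(ConfigurationError):
            detect_clash(frame, [0], [1], np.array(["C", "Xx"]), criteria)


class TestOracleAgreement:
    """Every detector agrees with the pure-python brute-force oracle."""

    N_FRAMES = 100

    def _random_frame(self, rng, n=14, box=8.0):
        return rng.uniform(-box, box, size=(n, 3))

    def test_ionic_and_hydrophobic_and_clash(self, criteria, rng):
        elements = np.array(["C", "N", "O", "C", "S", "C", "N", "C",
                             "O", "C", "C", "N", "C", "O"])
        idx_a, idx_b = [0, 1, 2, 3], [8, 9, 10, 11, 12, 13]
        for _ in range(self.N_FRAMES):
            frame = self._random_frame(rng)
            got = detect_ionic(frame, idx_a, idx_b, criteria) is not None
            assert got == oracles.brute_ionic(frame, idx_a, idx_b,
                                              criteria.ionic_max_dist)
            got = detect_hydrophobic(frame, idx_a, idx_b, criteria,
                                     elements=elements) is not None
            assert got == oracles.brute_hydrophobic(
                frame, idx_a, idx_b, elements, criteria.hydrophobic_max_dist)
            got = len(detect_clash(frame, idx_a, idx_b, elements, criteria))
            assert got == oracles.brute_clash_count(
                frame, idx_a, idx_b, elements, criteria.vdw_radii,
                criteria.clash_overlap)

    def test_hbond_and_water(self, criteria, rng):
        for _ in range(self.N_FRAMES):
            frame = self._random_frame(rng, n=10, box=5.0)
            got = detect_hbond(frame, [0, 1], [2, 3], criteria,
                               donor_root_idx=[4]) is not None
            assert got == oracles.brute_hbond(
                frame, [0, 1], [2, 3], criteria.hbond_max_dist,
                criteria.hbond_min_angle, root_idx=[4])
            waters = {1: np.array([5]), 2: np.array([6])}
            got = detect_water_mediated(frame, [0, 1], [2, 3], waters,
                                        criteria) is not None
            assert got == oracles.brute_water_mediated(
                frame, [0, 1], [2, 3], waters, criteria.hbond_max_dist)

    def test_cation_pi(self, criteria, rng):
        ring = np.asarray(hexagon([0, 0, 0]))
        for _ in range(self.N_FRAMES):
            cation = rng.uniform(-7, 7, size=(2, 3))
            frame = np.vstack([ring, cation])
            got = detect_cation_pi(frame, [6, 7], list(range(6)),
                                   criteria) is not None
            assert got == oracles.brute_cation_pi(
                frame, [6, 7], list(range(6)), criteria.cationpi_max_dist,
                criteria.cationpi_max_offset_angle)


class TestProperties:
    @given(d=st.floats(0.5, 12.0), cutoff=st.floats(1.0, 8.0),
           shrink=st.floats(0.1, 0.99))
    @settings(max_examples=60, deadline=None)
    def test_shrinking_cutoff_never_creates_events(self, d, cutoff, shrink):
        frame = frame_of([0, 0, 0], [0, 0, d])
        wide = GeometricCriteria(ionic_max_dist=cutoff)
        narrow = GeometricCriteria(ionic_max_dist=cutoff * shrink)
        if detect_ionic(frame, [0], [1], narrow) is not None:
            assert detect_ionic(frame, [0], [1], wide) is not None

    @given(st.lists(st.floats(-8, 8), min_size=6, max_size=6))
    @settings(max_examples=60, deadline=None)
    def test_ionic_symmetric_under_swap(self, coords):
        frame = np.asarray(coords).reshape(2, 3)
        crit = GeometricCriteria()
        a = detect_ionic(frame, [0], [1], crit)
        b = detect_ionic(frame, [1], [0], crit)
        assert (a is None) == (b is None)
        if a is not None:
            assert a.distance == pytest.approx(b.distance)

    def test_positive_event_distance_below_cutoff(self, criteria, rng):
        for _ in range(50):
            frame = rng.uniform(-6, 6, size=(4, 3))
            event = detect_ionic(frame, [0, 1], [2, 3], criteria)
            if event is not None:
                assert event.distance <= criteria.ionic_max_dist
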