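import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crowdsim.stimuli import (
    Stimulus,
    StimulusSet,
    make_contour_field,
    make_flanked_target,
    make_parkes_array,
    normalize_orientation,
    read_stimuli,
    write_stimuli,
)


@given(theta=st.floats(-1e4, 1e4, allow_nan=False))
@settings(deadline=None, max_examples=200)
def test_orientation_normalized_into_halfopen_interval(theta):
    s = Stimulus(theta, 1.0, (1.0, 0.0), 1.0)
    assert -90.0 <= s.orientation < 90.0
    # same orientation modulo 180
    assert math.isclose(
        math.cos(math.radians(2 * (s.orientation - theta))), 1.0, abs_tol=1e-6
    )


@pytest.mark.parametrize("bad", [dict(size=0), dict(size=-1), dict(contrast=0),
                                 dict(contrast=1.5)])
def test_invalid_stimulus_rejected(bad):
    kwargs = dict(orientation=0.0, size=1.0, location=(1.0, 0.0), contrast=1.0)
    kwargs.update(bad)
    with pytest.raises(ValueError):
        Stimulus(**kwargs)


class TestFlankedTarget:
    def test_radial_both_sides_collinear_eccentricities(self):
        s = make_flanked_target(10, 6, [30, 30], 2, "radial", "both", 1, 1, 1)
        assert len(s) == 3
        eccs = sorted(round(x.eccentricity, 9) for x in s)
        assert eccs == [4, 6, 8]
        assert all(x.location[1] == 0 for x in s)  # collinear through fixation
        assert s.target.location == (6.0, 0.0)

    def test_zero_spacing_collapses_all_locations(self):
        s = make_flanked_target(10, 6, [30, 30], 0, "radial", "both", 1, 1, 1)
        assert len({x.location for x in s}) == 1

    def test_single_foveal_flanker(self):
        s = make_flanked_target(10, 6, [30], 2, "radial", "foveal", 1, 1, 1)
        assert len(s) == 2
        flanker = s[1]
        assert flanker.eccentricity == pytest.approx(4.0)

    def test_tangential_flankers_perpendicular_offset(self):
        s = make_flanked_target(10, 6, [30, 30], 2, "tangential", "both", 1, 1, 1)
        ys = sorted(x.location[1] for x in s)
        assert ys == [-2.0, 0.0, 2.0]
        assert all(x.location[0] == 6.0 for x in s)

    def test_negative_eccentricity_flanker_rejected(self):
        with pytest.raises(ValueError, match="negative eccentricity"):
            make_flanked_target(10, 2, [30, 30], 3, "radial", "both", 1, 1, 1)


class TestParkesArray:
    def test_all_targets_all_tilted(self):
        rng = np.random.default_rng(0)
        s = make_parkes_array(9, 9, 4.0, 0.0, 2.5, 0.5, 0.5, 0.5, rng=rng)
        assert len(s) == 9
        assert all(x.orientation == pytest.approx(4.0) for x in s)

    def test_one_target_eight_vertical(self):
        rng = np.random.default_rng(0)
        s = make_parkes_array(1, 9, 4.0, 0.0, 2.5, 0.5, 0.5, 0.5, rng=rng)
        tilts = [x.orientation for x in s]
        assert sum(t != 0 for t in tilts) == 1
        assert sum(t == 0 for t in tilts) == 8

    def test_center_is_always_a_target(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            s = make_parkes_array(3, 9, 4.0, 0.0, 2.5, 0.5, 0.5, 0.5, rng=rng)
            assert s.target.location == (2.5, 0.0)
            assert s.target.orientation == pytest.approx(4.0)

    def test_same_seed_same_assignment(self):
        a = make_parkes_array(4, 9, rng=np.random.default_rng(42))
        b = make_parkes_array(4, 9, rng=np.random.default_rng(42))
        assert [x.orientation for x in a] == [x.orientation for x in b]
        assert [x.location for x in a] == [x.location for x in b]

    def test_ring_radius_equals_spacing(self):
        s = make_parkes_array(9, 9, 4.0, 0.0, 2.5, 0.5, rng=np.random.default_rng(1))
        center = np.array([2.5, 0.0])
        ring = [np.hypot(*(np.array(x.location) - center)) for x in s][1:]
        assert np.allclose(ring, 0.5)

    def test_no_flankers_condition_emits_only_targets(self):
        s = make_parkes_array(3, 9, 4.0, with_flankers=False,
                              rng=np.random.default_rng(3))
        assert len(s) == 3
        assert all(x.orientation == pytest.approx(4.0) for x in s)

    def test_too_many_targets_rejected(self):
        with pytest.raises(ValueError):
            make_parkes_array(10, 9)


class TestContourField:
    def test_contour_segment_count_and_contrast(self):
        s = make_contour_field(seed=0)
        assert len(s) > 127
        assert all(x.contrast == pytest.approx(0.8) for x in s)
        assert all(x.size == pytest.approx(0.8) for x in s)

    def test_circle_segments_tangential(self):
        s = make_contour_field(seed=0)
        for seg in list(s)[:35]:
            x, y = seg.location
            assert math.hypot(x, y - 10.0) == pytest.approx(4.0, abs=1e-9)
            # orientation perpendicular to the radius from (0, 10)
            radius_dir = math.degrees(math.atan2(y - 10.0, x))
            tangent_orientation = (90.0 - (radius_dir + 90.0) + 90.0) % 180.0 - 90.0
            diff = (seg.orientation - tangent_orientation + 90.0) % 180.0 - 90.0
            assert abs(diff) < 1e-6

    def test_open_contour_spacing(self):
        s = make_contour_field(seed=1)
        for c in range(4):
            seg = list(s)[35 + 23 * c : 35 + 23 * (c + 1)]
            pts = np.array([x.location for x in seg])
            steps = np.hypot(*np.diff(pts, axis=0).T)
            assert np.allclose(steps, 0.7, atol=1e-9)

    def test_seed_reproducibility(self):
        a, b = make_contour_field(seed=5), make_contour_field(seed=5)
        assert [x.orientation for x in a] == [x.orientation for x in b]
        c = make_contour_field(seed=6)
        assert [x.orientation for x in a] != [x.orientation for x in c]


class TestStimulusIO:
    def test_round_trip(self, tmp_path):
        s = make_flanked_target(10, 6, [30, -30], 2, "radial", "both", 0.7, 1, 1)
        p = tmp_path / "stims.tsv"
        write_stimuli(s, p)
        r = read_stimuli(p)
        assert r.target_index == s.target_index
        for a, b in zip(s, r):
            assert a == b

    def test_orientation_normalized_on_read(self, tmp_path):
        p = tmp_path / "stims.tsv"
        p.write_text(
            "orientation_deg\tsize\tx_deg\ty_deg\tcontrast\n95\t1\t1\t0\t1\n"
        )
        r = read_stimuli(p)
        assert r[0].orientation == pytest.approx(-85.0)

    def test_missing_column_error(self, tmp_path):
        p = tmp_path / "stims.tsv"
        p.write_text("orientation_deg\tsize\tx_deg\ty_deg\n0\t1\t1\t0\n")
        with pytest.raises(ValueError, match="contrast"):
            read_stimuli(p)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        p = tmp_path / "stims.tsv"
        p.write_text(
            "orientation_deg\tsize\tx_deg\ty_deg\tcontrast\n0\tfoo\t1\t0\t1\n"
        )
        with pytest.raises(ValueError, match="row 2.*'size'"):
            read_stimuli(p)

    def test_nonpositive_contrast_error(self, tmp_path):
        p = tmp_path / "stims.tsv"
        p.write_text(
            "orientation_deg\tsize\tx_deg\ty_deg\tcontrast\n0\t1\t1\t0\t0\n"
        )
        with pytest.raises(ValueError, match="contrast"):
            read_stimuli(p)

    def test_two_targets_rejected(self, tmp_path):
        p = tmp_path / "stims.tsv"
        p.write_text(
            "orientation_deg\tsize\tx_deg\ty_deg\tcontrast\tis_target\n"
            "0\t1\t1\t0\t1\t1\n5\t1\t2\t0\t1\t1\n"
        )
        with pytest.raises(ValueError, match="multiple rows"):
            read_stimuli(p)


def test_target_index_bounds_checked():
    with pytest.raises(ValueError):
        StimulusSet([Stimulus(0, 1, (1, 0), 1)], target_index=3)
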