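"""Biplane fusion, OCT completion/alignment, lofting and branch merging."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stentsim.reconstruction import (
    TubeField,
    align_pullback,
    centerline_from_biplane,
    complete_outer_contour,
    loft_branch,
    merge_branches,
    slice_profile,
)
from stentsim.synthetic import (
    AnatomyParams,
    Stenosis,
    generate_bifurcation,
    generate_oct_pullback,
    project_to_planes,
)


def polyline_distance(points, polyline):
    """Mean distance from query points to a dense polyline."""
    from scipy.spatial import cKDTree

    from stentsim.geometry import resample_polyline

    dense = resample_polyline(polyline, 20 * len(polyline))
    d, _ = cKDTree(dense).query(points)
    return float(d.mean())


class TestBiplaneFusion:
    def test_helix_round_trip_within_tolerance(self):
        t = np.linspace(0, 4 * np.pi, 300)
        helix = np.column_stack([5 * np.cos(t), 5 * np.sin(t), 2 * t])
        ca, cb = project_to_planes(helix, 0.0, 90.0)
        cl = centerline_from_biplane(ca, cb, n=300)
        assert polyline_distance(cl.points, helix) <= 0.05

    def test_straight_segment_exact(self):
        line = np.column_stack(
            [np.full(50, 1.0), np.full(50, 2.0), np.linspace(0, 30, 50)]
        )
        ca, cb = project_to_planes(line, 10.0, 100.0)
        cl = centerline_from_biplane(ca, cb, n=50)
        assert np.allclose(cl.points[:, 0], 1.0, atol=1e-9)
        assert np.allclose(cl.points[:, 1], 2.0, atol=1e-9)

    def test_identical_views_rejected(self):
        line = np.column_stack([np.zeros(10), np.zeros(10), np.linspace(0, 10, 10)])
        ca, cb = project_to_planes(line, 0.0, 45.0)
        cb = dataclasses.replace(cb, view_angle=0.0)
        with pytest.raises(ValueError):
            centerline_from_biplane(ca, cb)

    def test_length_mismatch_warns_but_fits(self):
        line = np.column_stack([np.zeros(40), np.zeros(40), np.linspace(0, 30, 40)])
        ca, cb = project_to_planes(line, 0.0, 90.0)
        short = dataclasses.replace(cb, points=cb.points[:25])
        with pytest.warns(UserWarning, match="20%"):
            centerline_from_biplane(ca, short)


from functools import lru_cache


@lru_cache(maxsize=1)
def _reference_frame():
    an = generate_bifurcation(AnatomyParams(stenoses=(Stenosis("MV", 32.0, 0.6, 8.0),)))
    return generate_oct_pullback(an, "MV", 0.5).frames[5]


def frame_with_missing(frame, start, end):
    outer = frame.outer_radius.copy()
    mask_start, mask_end = start % 360.0, end % 360.0
    ang = frame.angles_deg
    if mask_start <= mask_end:
        m = (ang >= mask_start) & (ang < mask_end)
    else:
        m = (ang >= mask_start) | (ang < mask_end)
    outer[m] = np.nan
    return dataclasses.replace(
        frame, outer_radius=outer, missing_arcs=((start % 360.0, end % 360.0),)
    )


@pytest.fixture(scope="module")
def base_frame(stenosed_anatomy):
    return generate_oct_pullback(stenosed_anatomy, "MV", 0.5).frames[10]


class TestOuterBorderRule:

    def test_small_gap_interpolated(self, base_frame):
        f = frame_with_missing(base_frame, 30.0, 120.0)
        completed, discard = complete_outer_contour(f)
        assert not discard
        assert np.isfinite(completed.outer_radius).all()
        # constant-radius truth: periodic interpolation is exact
        np.testing.assert_allclose(
            completed.outer_radius, base_frame.outer_radius, atol=1e-6
        )

    def test_large_gap_discarded(self, base_frame):
        _, discard = complete_outer_contour(frame_with_missing(base_frame, 30.0, 230.0))
        assert discard

    def test_exactly_180_interpolated(self, base_frame):
        _, discard = complete_outer_contour(frame_with_missing(base_frame, 0.0, 180.0))
        assert not discard

    def test_complete_frame_returned_unchanged(self, base_frame):
        same, discard = complete_outer_contour(base_frame)
        assert same is base_frame and not discard

    @given(st.floats(0, 359.9), st.floats(5.0, 355.0))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_rule_is_pure_function_of_missing_span(self, start, span):
        frame = _reference_frame()
        f = frame_with_missing(frame, start, start + span)
        _, discard = complete_outer_contour(f)
        total = f.total_missing_deg
        assert discard == (total > 180.0)


class TestAlignAndLoft:
    def test_carina_frame_lands_on_carina(self, stenosed_anatomy):
        pb = generate_oct_pullback(stenosed_anatomy, "MV", 0.5)
        placed = align_pullback(pb, stenosed_anatomy.mv.centerline)
        s = [p.arclength for p in placed]
        assert min(abs(x - stenosed_anatomy.carina_arclength) for x in s) < 1e-9

    def test_uniform_spacing_arithmetic(self, stenosed_anatomy):
        pb = generate_oct_pullback(stenosed_anatomy, "MV", 0.5)
        placed = align_pullback(pb, stenosed_anatomy.mv.centerline)
        s = np.array([p.arclength for p in placed])
        assert np.allclose(np.diff(s), 0.5, atol=1e-9)

    def test_aligned_areas_match_generator_profile(self, stenosed_anatomy):
        pb = generate_oct_pullback(stenosed_anatomy, "MV", 0.5)
        placed = align_pullback(pb, stenosed_anatomy.mv.centerline)
        s, a, _d = slice_profile(placed, 0.5)
        truth = np.pi * (np.asarray(stenosed_anatomy.mv.diameter_at(s)) / 2) ** 2
        assert np.max(np.abs(a - truth) / truth) < 0.01

    def test_cylinder_loft_area(self, clean_anatomy):
        pb = generate_oct_pullback(clean_anatomy, "MV", 0.5)
        placed = align_pullback(pb, clean_anatomy.mv.centerline)
        mesh = loft_branch(placed)
        assert mesh.is_watertight
        truth = np.pi * 3.0 * 40.0 + 2 * np.pi * 1.5**2  # lateral + caps
        assert mesh.area == pytest.approx(truth, rel=0.005)

    def test_discarded_interior_frame_lofted_across(self, clean_anatomy):
        pb = generate_oct_pullback(clean_anatomy, "MV", 0.5)
        placed = align_pullback(pb, clean_anatomy.mv.centerline)
        placed[20].discarded = True
        mesh = loft_branch(placed)
        assert mesh.is_watertight  # no hole where the frame was dropped

    def test_stenosis_minimum_area_recovered(self, stenosed_anatomy):
        pb = generate_oct_pullback(stenosed_anatomy, "MV", 0.25)
        placed = align_pullback(pb, stenosed_anatomy.mv.centerline)
        _s, a, _d = slice_profile(placed, 0.25)
        truth_min = np.pi * (stenosed_anatomy.mv.diameter.min() / 2) ** 2
        assert a.min() == pytest.approx(truth_min, rel=0.02)

    def test_too_few_frames_rejected(self, clean_anatomy):
        pb = generate_oct_pullback(clean_anatomy, "MV", 0.5)
        placed = align_pullback(pb, clean_anatomy.mv.centerline)
        for p in placed[1:]:
            p.discarded = True
        with pytest.raises(ValueError):
            loft_branch(placed)

    def test_loft_area_converges_under_refinement(self, stenosed_anatomy):
        areas = {}
        for spacing in (1.0, 0.5):
            pb = generate_oct_pullback(stenosed_anatomy, "MV", spacing)
            placed = align_pullback(pb, stenosed_anatomy.mv.centerline)
            areas[spacing] = loft_branch(placed).area
        assert abs(areas[0.5] - areas[1.0]) / areas[1.0] < 0.01


@pytest.fixture(scope="module")
def merged(stenosed_anatomy):
    an = stenosed_anatomy
    return merge_branches(
        TubeField(an.mv.centerline.points, an.mv.diameter / 2),
        TubeField(an.sb.centerline.points, an.sb.diameter / 2),
        an.carina_point,
        mv_centerline=an.mv.centerline,
        sb_centerline=an.sb.centerline,
        bifurcation_angle_deg=an.params.bifurcation_angle,
        sb_radius=an.params.sb_diameter / 2,
        pitch=0.2,
    )


class TestMergeBranches:
    def test_watertight_union(self, merged):
        assert merged.lumen.is_watertight

    def test_volume_contains_both_branches(self, merged, stenosed_anatomy):
        mv_vol = stenosed_anatomy.surface("MV", "lumen").volume
        sb_vol = stenosed_anatomy.surface("SB", "lumen").volume
        assert merged.lumen.volume >= max(mv_vol, sb_vol)

    def test_ostium_area_matches_oblique_ellipse(self, merged):
        r_sb = 1.25
        truth = np.pi * r_sb**2 / np.sin(np.deg2rad(60.0))
        assert merged.sb_ostium_area == pytest.approx(truth, rel=0.10)

    def test_disjoint_branches_rejected(self, stenosed_anatomy):
        an = stenosed_anatomy
        far = an.sb.centerline.points + np.array([50.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="intersect"):
            merge_branches(
                TubeField(an.mv.centerline.points, an.mv.diameter / 2),
                TubeField(far, an.sb.diameter / 2),
                an.carina_point,
            )


class TestSliceProfile:
    def test_cylinder_diameters(self, clean_anatomy):
        pb = generate_oct_pullback(clean_anatomy, "MV", 0.5)
        placed = align_pullback(pb, clean_anatomy.mv.centerline)
        _s, _a, d = slice_profile(placed, 0.5)
        assert np.allclose(d, 3.0, rtol=0.002)

    def test_stenosis_dip_fraction(self, stenosed_anatomy):
        pb = generate_oct_pullback(stenosed_anatomy, "MV", 0.25)
        placed = align_pullback(pb, stenosed_anatomy.mv.centerline)
        s, _a, d = slice_profile(placed, 0.25)
        ref = np.asarray(stenosed_anatomy.mv.healthy_diameter_at(s))
        assert (d / ref).min() == pytest.approx(0.4, abs=0.01)

    def test_refinement_stability(self, stenosed_anatomy):
        pb = generate_oct_pullback(stenosed_anatomy, "MV", 0.25)
        placed = align_pullback(pb, stenosed_anatomy.mv.centerline)
        s1, _a, d1 = slice_profile(placed, 0.5)
        s2, _a2, d2 = slice_profile(placed, 0.25)
        interp = np.interp(s1, s2, d2)
        assert np.max(np.abs(interp - d1) / d1) < 0.01

    def test_invalid_spacing(self, clean_anatomy):
        pb = generate_oct_pullback(clean_anatomy, "MV", 0.5)
        placed = align_pullback(pb, clean_anatomy.mv.centerline)
        with pytest.raises(ValueError):
            slice_profile(placed, 0.0)
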