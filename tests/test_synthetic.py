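"""Synthetic anatomy, OCT pullback, projection and procedure generation."""

import numpy as np
import pytest

from stentsim.procedures import ProcedureTable
from stentsim.synthetic import (
    AnatomyParams,
    CompositionZone,
    Stenosis,
    default_devices,
    generate_bench_variant,
    generate_bifurcation,
    generate_oct_pullback,
    generate_procedure,
    project_to_planes,
)


class TestGenerateBifurcation:
    def test_identity_profile_without_taper_or_stenosis(self):
        an = generate_bifurcation(
            AnatomyParams(proximal_mv_diameter=3.5, distal_mv_diameter=3.5)
        )
        assert np.allclose(an.mv.diameter, 3.5)

    def test_stenosis_minimum_diameter(self):
        an = generate_bifurcation(
            AnatomyParams(
                proximal_mv_diameter=3.0,
                distal_mv_diameter=3.0,
                stenoses=(Stenosis("MV", 32.0, 0.6, 8.0),),
            )
        )
        assert an.mv.diameter.min() == pytest.approx(3.0 * (1 - 0.6), rel=1e-12)

    def test_deterministic_for_fixed_seed(self):
        p = AnatomyParams(stenoses=(Stenosis("MV", 32.0, 0.6, 8.0),), seed=3)
        a, b = generate_bifurcation(p), generate_bifurcation(p)
        assert np.array_equal(a.mv.centerline.points, b.mv.centerline.points)
        assert np.array_equal(a.mv.diameter, b.mv.diameter)
        assert np.array_equal(a.sb.composition, b.sb.composition)

    def test_stenosis_at_carina_rejected(self):
        with pytest.raises(ValueError, match="carina"):
            generate_bifurcation(
                AnatomyParams(stenoses=(Stenosis("MV", 20.0, 0.5, 8.0),))
            )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AnatomyParams(proximal_mv_diameter=-1.0)
        with pytest.raises(ValueError):
            AnatomyParams(proximal_mv_diameter=3.0, distal_mv_diameter=3.5)
        with pytest.raises(ValueError):
            Stenosis("MV", 10.0, 1.0, 5.0)

    def test_surfaces_watertight(self, stenosed_anatomy):
        for branch in ("MV", "SB"):
            assert stenosed_anatomy.surface(branch, "lumen").is_watertight
        assert stenosed_anatomy.surface("MV", "outer").is_watertight

    def test_curved_mv_follows_arc(self):
        an = generate_bifurcation(AnatomyParams(curvature_radius=50.0))
        # all centerline points at distance 50 from the arc center (50, 0, 0)
        d = np.linalg.norm(an.mv.centerline.points - np.array([50.0, 0, 0]), axis=1)
        assert np.allclose(d, 50.0, atol=1e-9)


class TestOCTPullback:
    def test_frame_count(self, stenosed_anatomy):
        pb = generate_oct_pullback(stenosed_anatomy, "SB", frame_spacing=0.5)
        # 20 mm branch at 0.5 mm -> floor(20/0.5)+1 = 41 frames
        assert len(pb.frames) == 41

    def test_no_dropout_means_complete_outer_borders(self, stenosed_anatomy):
        pb = generate_oct_pullback(stenosed_anatomy, "MV", 0.5, seed=2)
        assert all(np.isfinite(f.outer_radius).all() for f in pb.frames)
        assert all(f.missing_arcs == () for f in pb.frames)

    def test_carina_frame_at_carina_arclength(self, stenosed_anatomy):
        pb = generate_oct_pullback(stenosed_anatomy, "MV", 0.5)
        s_carina_frame = pb.frames[pb.carina_frame_index].arclength
        assert abs(s_carina_frame - stenosed_anatomy.carina_arclength) <= 0.25 + 1e-9

    def test_spacing_longer_than_branch_rejected(self, stenosed_anatomy):
        with pytest.raises(ValueError):
            generate_oct_pullback(stenosed_anatomy, "SB", frame_spacing=25.0)

    def test_frame_area_matches_analytic_profile(self, stenosed_anatomy):
        """64-point polygon areas within 1% of the analytic circle areas."""
        pb = generate_oct_pullback(stenosed_anatomy, "MV", 0.5)
        for f in pb.frames[::10]:
            truth = np.pi * (stenosed_anatomy.mv.diameter_at(f.arclength) / 2) ** 2
            assert f.lumen_area() == pytest.approx(truth, rel=0.01)

    def test_composition_arcs_cover_requested_fractions(self):
        an = generate_bifurcation(
            AnatomyParams(
                stenoses=(Stenosis("MV", 32.0, 0.5, 8.0),),
                composition_zones=(CompositionZone("MV", 28.0, 36.0, (0.3, 0.5, 0.2)),),
            )
        )
        pb = generate_oct_pullback(an, "MV", 0.5, seed=5)
        bin_deg = 360.0 / 64
        lesion = [f for f in pb.frames if 29.0 <= f.arclength <= 35.0]
        assert lesion
        for f in lesion:
            spans = {}
            for s, e, tissue, _t in f.composition_arcs:
                spans[tissue] = spans.get(tissue, 0.0) + (e - s) % 360.0
            assert spans["lipid"] == pytest.approx(0.3 * 360, abs=bin_deg)
            assert spans["fibrous"] == pytest.approx(0.5 * 360, abs=bin_deg)
            assert spans["calcified"] == pytest.approx(0.2 * 360, abs=bin_deg)

    def test_dropout_sampler_injects_missing_arcs(self, stenosed_anatomy):
        pb = generate_oct_pullback(
            stenosed_anatomy,
            "MV",
            0.5,
            dropout_arcs=lambda rng, i: [(30.0, 120.0)] if i % 2 == 0 else [],
            seed=1,
        )
        assert pb.frames[0].missing_arcs == ((30.0, 120.0),)
        assert np.isnan(pb.frames[0].outer_radius).any()
        assert not np.isnan(pb.frames[1].outer_radius).any()

    def test_export_round_trip(self, stenosed_anatomy, tmp_path):
        pb = generate_oct_pullback(stenosed_anatomy, "SB", 1.0, seed=0)
        pb.export(tmp_path)
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "frame_0000.csv").read_text().startswith("angle_deg,")


class TestProjections:
    def test_separation_below_30_degrees_rejected(self, stenosed_anatomy):
        with pytest.raises(ValueError, match="30 degrees"):
            project_to_planes(stenosed_anatomy, 0.0, 20.0)

    def test_orthogonal_views_of_helix_differ(self):
        t = np.linspace(0, 4 * np.pi, 200)
        helix = np.column_stack([5 * np.cos(t), 5 * np.sin(t), 2 * t])
        ca, cb = project_to_planes(helix, 0.0, 90.0)
        assert not np.allclose(ca.points, cb.points)

    def test_planar_curve_projected_along_normal_is_exact(self):
        # curve in the y-z plane viewed along x (view angle 0)
        pts = np.column_stack([np.zeros(50), np.linspace(-5, 5, 50), np.linspace(0, 20, 50)])
        ca, _ = project_to_planes(pts, 0.0, 90.0)
        assert np.allclose(ca.points[:, 0], pts[:, 1])
        assert np.allclose(ca.points[:, 1], pts[:, 2])


class TestBenchVariant:
    def test_uniform_offset_and_material(self, stenosed_anatomy):
        bench = generate_bench_variant(stenosed_anatomy, silicone_thickness=1.0)
        assert np.allclose(bench.anatomy.mv.wall_thickness, 1.0)
        assert np.allclose(bench.anatomy.sb.wall_thickness, 1.0)
        assert bench.c10() == 0.154

    def test_plaque_score_undefined(self, stenosed_anatomy):
        bench = generate_bench_variant(stenosed_anatomy, 1.0)
        assert bench.plaque_score("MV", 32.0) is None

    def test_invalid_thickness(self, stenosed_anatomy):
        with pytest.raises(ValueError):
            generate_bench_variant(stenosed_anatomy, 0.0)


class TestProcedureGeneration:
    def test_provisional_sequence(self):
        table = generate_procedure("provisional", default_devices())
        assert [s.action for s in table.steps] == ["stent", "pot", "sb_open", "kbi"]
        assert table.steps[0].branch == "MV"

    def test_culotte_has_two_stents_on_different_branches(self):
        table = generate_procedure("culotte", default_devices())
        stents = [s for s in table.steps if s.action == "stent"]
        assert len(stents) == 2
        assert {s.branch for s in stents} == {"MV", "SB"}

    def test_empty_devices_rejected(self):
        with pytest.raises(ValueError, match="device"):
            generate_procedure("provisional", {})

    def test_unknown_template_rejected(self):
        with pytest.raises(ValueError, match="template"):
            generate_procedure("crush", default_devices())

    def test_yaml_round_trip(self, tmp_path):
        table = generate_procedure("TAP", default_devices())
        path = tmp_path / "tap.yaml"
        table.to_yaml(path)
        again = ProcedureTable.from_yaml(path)
        assert again.to_yaml() == table.to_yaml()

    def test_forward_reference_rejected(self):
        table = generate_procedure("provisional", default_devices())
        d = table.to_dict()
        d["steps"][0]["placement"] = {
            "mode": "relative_to_step",
            "value_mm": 2.0,
            "reference_step": 3,
        }
        with pytest.raises(ValueError, match="later step"):
            ProcedureTable.from_dict(d)
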