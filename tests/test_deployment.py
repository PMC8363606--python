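"""Slice-equilibrium deployment surrogate: contracts and properties."""

import copy

import numpy as np
import pytest

from stentsim.deployment import (
    DeploymentConfig,
    RingLayer,
    SliceState,
    deflate_recoil,
    deploy_stent,
    inflate,
    initial_state,
    kbi,
    malapposition_map,
    pot,
    ring_pressure,
    run_procedure,
    sb_open,
    wall_pressure,
)
from stentsim.devices import BalloonSpec, balloon_diameter_at_pressure, design_from_preset
from stentsim.procedures import ProcedureTable
from stentsim.synthetic import default_devices, generate_bench_variant, generate_procedure

from conftest import plaque_anatomy


def silicone_slice(r0=1.75, t=1.0):
    return SliceState(arclength=0.0, r0=r0, r=r0, wall_thickness=t, material="silicone")


class TestWallPressure:
    def test_zero_at_reference(self, stenosed_state):
        for slc in stenosed_state.mv[::20]:
            assert wall_pressure(stenosed_state, slc, slc.r0) == 0.0

    def test_silicone_composes_with_material_law(self, stenosed_state):
        """p = (t/r) * sigma with the Neo-Hookean silicone stress at lam=1.1."""
        slc = silicone_slice()
        r = 1.1 * slc.r0
        expected = (1.0 / r) * 0.0927
        assert wall_pressure(stenosed_state, slc, r) == pytest.approx(expected, rel=1e-3)

    def test_monotone_before_yield_cap(self, stenosed_state):
        slc = silicone_slice()
        rs = np.linspace(slc.r0, 1.3 * slc.r0, 30)
        ps = [wall_pressure(stenosed_state, slc, r) for r in rs]
        assert all(b > a for a, b in zip(ps, ps[1:]))

    def test_stiff_plaque_resists_more_than_soft(self, stenosed_state):
        soft = SliceState(0.0, 1.0, 1.0, 0.9, material=-1.0, r_healthy=1.5)
        stiff = SliceState(0.0, 1.0, 1.0, 0.9, material=1.0, r_healthy=1.5)
        r = 1.2
        assert wall_pressure(stenosed_state, stiff, r) > wall_pressure(
            stenosed_state, soft, r
        )

    def test_radius_below_validity_rejected(self, stenosed_state):
        with pytest.raises(ValueError):
            wall_pressure(stenosed_state, silicone_slice(), 0.4)


class TestRingPressure:
    def layer(self, area=0.00785):
        return RingLayer(
            stent_id="s", alloy="MP35N", section_area=area, strut_thickness=0.1,
            r_ref=0.6, r_ring=0.6,
        )

    def test_zero_at_plastic_set(self, stenosed_state):
        layer = self.layer()
        assert ring_pressure(stenosed_state, layer, layer.r_set) == 0.0

    def test_elastic_slope_linear_in_section_area(self, stenosed_state):
        l1, l2 = self.layer(0.005), self.layer(0.010)
        r = 0.6 * (1 + 0.5 * 414.0 / 233e3)  # well below yield
        assert ring_pressure(stenosed_state, l2, r) == pytest.approx(
            2.0 * ring_pressure(stenosed_state, l1, r), rel=1e-12
        )

    def test_plastic_set_increases_after_yield(self, stenosed_state):
        from stentsim.deployment import _commit_ring

        layer = self.layer()
        _commit_ring(stenosed_state, layer, 1.5)  # far past yield strain
        assert layer.eps_p > 0.0
        assert layer.r_set > layer.r_ref

    def test_unloading_slope_is_elastic(self, stenosed_state):
        from stentsim.deployment import _commit_ring

        layer = self.layer()
        _commit_ring(stenosed_state, layer, 1.5)
        # reloading just below the new set is compressive, above is tensile
        assert ring_pressure(stenosed_state, layer, layer.r_set * 0.999) < 0.0
        assert ring_pressure(stenosed_state, layer, layer.r_set * 1.001) > 0.0


class TestInflateDeflate:
    def test_zero_pressure_is_identity(self, stenosed_state):
        before = stenosed_state.serialize()
        balloon = BalloonSpec(3.0, 26.0, unfold_pressure=0.5, nominal_pressure=8.0)
        inflate(stenosed_state, balloon, 0.4, (0.0, 40.0))
        assert stenosed_state.serialize() == before

    def test_pressure_monotonicity_per_slice(self, stenosed_anatomy):
        balloon = BalloonSpec(3.0, 26.0, compliance_class="semi_compliant")
        radii = {}
        for p in (6.0, 10.0, 14.0):
            st = initial_state(stenosed_anatomy)
            inflate(st, balloon, p, (24.0, 40.0))
            radii[p] = np.array([s.r for s in st.mv])
        assert np.all(radii[10.0] >= radii[6.0])
        assert np.all(radii[14.0] >= radii[10.0])

    def test_unstented_wall_clamped_at_balloon_radius(self, clean_anatomy):
        st = initial_state(clean_anatomy)
        balloon = BalloonSpec(3.6, 26.0, compliance_class="non_compliant")
        inflate(st, balloon, balloon.nominal_pressure, (0.0, 18.0))
        r_max = balloon_diameter_at_pressure(balloon, balloon.nominal_pressure) / 2.0
        dilated = [s for s in st.mv if s.arclength <= 18.0]
        assert all(s.r <= r_max + 1e-9 for s in dilated)
        assert all(s.r > s.r0 for s in dilated)  # compliant wall follows the balloon

    def test_unstented_recoil_returns_to_reference(self, stenosed_state):
        balloon = BalloonSpec(3.5, 15.0)
        inflate(stenosed_state, balloon, 10.0, (0.0, 15.0))
        deflate_recoil(stenosed_state, (0.0, 15.0))
        for slc in stenosed_state.mv:
            if slc.arclength <= 15.0:
                assert slc.r == slc.r0

    def test_recoil_never_increases_radius(self, stenosed_anatomy, mv_stent_design, mv_balloon):
        st = initial_state(stenosed_anatomy)
        deploy_stent(st, mv_stent_design, mv_balloon, 16.0, (24.0, 40.0))
        peak = [s.r for s in st.mv]
        deflate_recoil(st, (0.0, 40.0))
        assert all(b <= a + 1e-12 for a, b in zip(peak, [s.r for s in st.mv]))

    def test_stented_slice_retains_plastic_gain(self, stenosed_anatomy, mv_stent_design, mv_balloon):
        st = initial_state(stenosed_anatomy)
        deploy_stent(st, mv_stent_design, mv_balloon, 16.0, (24.0, 40.0))
        # lesion core: slices narrowed well below the balloon diameter
        lesion = [s for s in st.mv if 30.0 <= s.arclength <= 34.0 and s.layers]
        assert lesion
        assert all(s.r > s.r0 for s in lesion)


class TestDeployStent:
    def test_sb_untouched_by_mv_stent_away_from_ostium(
        self, stenosed_anatomy, mv_stent_design, mv_balloon
    ):
        st = initial_state(stenosed_anatomy)
        before = [s.r for s in st.sb]
        deploy_stent(st, mv_stent_design, mv_balloon, 16.0, (24.0, 40.0))
        assert [s.r for s in st.sb] == before

    def test_msd_bounded_by_balloon_diameter(self, stenosed_anatomy, mv_stent_design, mv_balloon):
        st = initial_state(stenosed_anatomy)
        deploy_stent(st, mv_stent_design, mv_balloon, 16.0, (24.0, 40.0))
        d_max = balloon_diameter_at_pressure(mv_balloon, 16.0)
        _s, msd = st.stent_profile("MV")
        assert np.all(msd <= d_max + 1e-9)

    def test_mv_stent_across_ostium_jails_sb(self, stenosed_anatomy, mv_balloon):
        design = design_from_preset("integrity_like", diameter_mm=3.0, length_mm=26.0)
        st = initial_state(stenosed_anatomy)
        deploy_stent(st, design, mv_balloon, 16.0, (10.0, 36.0))
        jailed = [s for s in st.sb if s.jailed]
        assert jailed and all(
            s.arclength - st.carina_arclength <= st.config.ostium_zone for s in jailed
        )

    def test_culotte_overlap_carries_two_layers(self, stenosed_anatomy):
        st = initial_state(stenosed_anatomy)
        table = generate_procedure("culotte", default_devices())
        run_procedure(st, table)
        overlap = [s for s in st.mv if len(s.layers) == 2]
        assert overlap  # proximal MV slices under both stents


class TestPOT:
    def test_distal_slices_unchanged(self, stenosed_state):
        before = [s.r for s in stenosed_state.mv if s.arclength > 20.0]
        pot(stenosed_state, BalloonSpec(3.5, 15.0, compliance_class="non_compliant"), 18.0)
        after = [s.r for s in stenosed_state.mv if s.arclength > 20.0]
        assert before == after

    def test_window_never_crosses_carina(self, stenosed_state):
        pot(
            stenosed_state,
            BalloonSpec(3.5, 15.0, compliance_class="non_compliant"),
            18.0,
            window=(15.0, 30.0),
        )
        assert all(s.r == s.r0 for s in stenosed_state.mv if s.arclength > 20.0)

    def test_proximal_mld_does_not_decrease(self, stenosed_anatomy, mv_stent_design, mv_balloon):
        st = initial_state(stenosed_anatomy)
        deploy_stent(st, mv_stent_design, mv_balloon, 12.0, (10.0, 36.0))
        before = np.array([s.r for s in st.mv if s.arclength <= 20.0])
        pot(st, BalloonSpec(3.5, 15.0, compliance_class="non_compliant"), 18.0)
        after = np.array([s.r for s in st.mv if s.arclength <= 20.0])
        assert np.all(after >= before - 1e-12) and after.max() > before.max()


class TestSBOpenAndKBI:
    def test_sb_open_increases_ostium_area_and_clears_jail(
        self, stenosed_anatomy, mv_balloon
    ):
        design = design_from_preset("integrity_like", diameter_mm=3.0, length_mm=26.0)
        st = initial_state(stenosed_anatomy)
        deploy_stent(st, design, mv_balloon, 16.0, (10.0, 36.0))
        area0 = st.sb_ostium_area()
        sb_open(st, BalloonSpec(2.5, 12.0, compliance_class="compliant"), 14.0)
        assert st.sb_ostium_area() > area0
        assert not any(s.jailed for s in st.sb)
        assert st.recross_cell == "distal"

    def test_sb_open_leaves_mv_unchanged(self, stenosed_state):
        before = stenosed_state.profile("MV")[1].copy()
        sb_open(stenosed_state, BalloonSpec(2.5, 12.0, compliance_class="compliant"), 14.0)
        assert np.array_equal(stenosed_state.profile("MV")[1], before)

    def test_kbi_equal_balloons_area_sum_clamp(self):
        """Combined clamp is sqrt(2) x the single-balloon radius."""
        r = balloon_diameter_at_pressure(BalloonSpec(3.0, 15.0), 10.0) / 2.0
        assert np.hypot(r, r) == pytest.approx(np.sqrt(2.0) * r)

    def test_kbi_proximal_mld_does_not_decrease(self, stenosed_anatomy, mv_stent_design, mv_balloon):
        st = initial_state(stenosed_anatomy)
        deploy_stent(st, mv_stent_design, mv_balloon, 16.0, (10.0, 36.0))
        before = np.array([s.r for s in st.mv if s.arclength <= 20.0])
        kbi(
            st,
            BalloonSpec(3.5, 15.0, compliance_class="compliant"),
            BalloonSpec(2.75, 8.0, compliance_class="semi_compliant"),
            12.0,
            14.0,
        )
        after = np.array([s.r for s in st.mv if s.arclength <= 20.0])
        assert np.all(after >= before - 1e-12)

    def test_kbi_distal_mv_unaffected(self, stenosed_anatomy):
        st = initial_state(stenosed_anatomy)
        before = [s.r for s in st.mv if s.arclength > 20.0]
        kbi(
            st,
            BalloonSpec(3.5, 15.0, compliance_class="compliant"),
            BalloonSpec(2.75, 8.0, compliance_class="semi_compliant"),
            12.0,
            14.0,
        )
        assert [s.r for s in st.mv if s.arclength > 20.0] == before


class TestMalapposition:
    def test_gaps_non_negative_and_zero_when_apposed(
        self, stenosed_anatomy, mv_stent_design, mv_balloon
    ):
        st = initial_state(stenosed_anatomy)
        deploy_stent(st, mv_stent_design, mv_balloon, 16.0, (24.0, 40.0))
        gaps = malapposition_map(st)
        assert gaps and all(g >= 0.0 for g in gaps.values())

    def test_undersized_stent_shows_positive_gap(self, clean_anatomy):
        """A 2.0 mm stent in a 3.0 mm vessel stays malapposed."""
        st = initial_state(clean_anatomy)
        design = design_from_preset("integrity_like", diameter_mm=2.0, length_mm=8.0)
        balloon = BalloonSpec(2.0, 8.0, compliance_class="non_compliant")
        deploy_stent(st, design, balloon, 8.0, (10.0, 18.0))
        gaps = malapposition_map(st)
        assert max(gaps.values()) > 0.2


class TestRunProcedure:
    def test_empty_table_returns_state_unchanged(self, stenosed_state):
        before = stenosed_state.serialize()
        run_procedure(stenosed_state, ProcedureTable("empty", []))
        assert stenosed_state.serialize() == before

    def test_provisional_sequence_completes(self, stenosed_anatomy):
        st = initial_state(stenosed_anatomy)
        table = generate_procedure("provisional", default_devices())
        log = []
        run_procedure(st, table, log=log)
        assert len(st.history) == len(table.steps)
        assert all("pressure_mpa" in e for e in log)
        assert log[0]["provenance"]["friction_coefficient"] == 0.2

    def test_bench_case_runs_on_silicone_model(self, stenosed_anatomy):
        from stentsim.deployment import bench_state

        bench = generate_bench_variant(stenosed_anatomy, 1.0)
        st = bench_state(bench)
        assert all(s.material == "silicone" for s in st.mv)
        table = generate_procedure("provisional", default_devices())
        run_procedure(st, table)
        assert st.profile("MV")[1].max() > 3.0

    def test_balloon_step_before_stent_warns(self, stenosed_state):
        table = generate_procedure("provisional", default_devices())
        reordered = ProcedureTable("odd", [table.steps[1], table.steps[0]])
        with pytest.warns(UserWarning, match="ordering"):
            run_procedure(stenosed_state, reordered)

    def test_step_chaining_is_bitwise_reproducible(self, stenosed_anatomy):
        table = generate_procedure("provisional", default_devices())
        full = initial_state(stenosed_anatomy)
        run_procedure(full, table)
        part = initial_state(stenosed_anatomy)
        run_procedure(part, ProcedureTable("a", table.steps[:2]))
        resumed = copy.deepcopy(part)
        run_procedure(resumed, ProcedureTable("b", table.steps[2:]))
        assert resumed.serialize() == full.serialize()

    def test_stiff_lesion_underexpands_relative_to_soft(self, mv_stent_design, mv_balloon):
        """Identical procedure, score +1 vs -1 lesion: stiffer ends smaller."""
        mld = {}
        for sign in (-1, 1):
            st = initial_state(plaque_anatomy(sign))
            deploy_stent(st, mv_stent_design, mv_balloon, 16.0, (24.0, 40.0))
            s, d = st.profile("MV")
            mld[sign] = d[(s >= 28.0) & (s <= 36.0)].min()
        assert mld[1] < mld[-1]

    def test_slice_spacing_convergence_below_1pct(self, stenosed_anatomy):
        """Halving 0.50 -> 0.25 mm changes the final MLD profile < 1%."""
        table = generate_procedure("provisional", default_devices())
        prof = {}
        for spacing in (0.5, 0.25):
            st = initial_state(stenosed_anatomy, DeploymentConfig(slice_spacing=spacing))
            run_procedure(st, table)
            prof[spacing] = st.profile("MV")
        s_c, d_c = prof[0.25]
        s_f, d_f = prof[0.5]
        interp = np.interp(s_f, s_c, d_c)
        assert np.max(np.abs(interp - d_f) / d_f) < 0.01
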