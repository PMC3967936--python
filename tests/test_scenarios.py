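"""Whole-epithelium runs: wild-type pattern, mutants and clones.

These checks are qualitative pattern invariants (patch counts, footprints,
autonomy), asserted on the attractor configurations of the bundled
scenarios.
"""

import numpy as np
import pytest

from epilogic import eggshell
from epilogic.hexgrid import HexGrid


class TestWildtype:
    def test_both_phases_reach_fixed_points(self, wt):
        assert wt.outcome_pre.kind == "fixed_point"
        assert wt.outcome_post.kind == "fixed_point"

    def test_two_mirror_roof_patches(self, wt, fates):
        _, summary = eggshell.classify_pattern(wt.epi_post, fates)
        assert summary["n_roof_patches"] == 2
        a, b = summary["roof_patch_sizes"]
        assert a == b  # mirror images about the dorsal midline

    def test_extinction_changes_rho_pnt_aos_but_not_br(self, wt):
        assert np.array_equal(wt.epi_pre.fields["Br"], wt.epi_post.fields["Br"])
        for name in ("Rho", "Pnt", "Aos"):
            assert not np.array_equal(
                wt.epi_pre.fields[name], wt.epi_post.fields[name]
            ), name

    def test_floor_single_cell_wide_touching_roof(self, wt, fates):
        _, summary = eggshell.classify_pattern(wt.epi_post, fates)
        assert summary["n_floor_cells"] > 0
        assert summary["floor_all_touch_roof"]
        # a one-cell-wide path has at most 2 floor neighbors per cell
        assert summary["floor_max_floor_neighbors"] <= 2

    def test_floor_on_operculum_side(self, wt):
        """Floor limbs sit dorsally/anteriorly of the roof patches, never on
        the ventral-lateral or posterior borders."""
        grid = wt.epi_post.grid
        params = eggshell.WildtypeParams()
        floor = wt.epi_post.fields["Rho"] == 2
        grk = wt.epi_pre.fields["Grk"]
        mid = wt.epi_post.fields["Mid"]
        for cell in grid.cells():
            if floor[cell]:
                assert mid[cell] == 0
                assert grk[cell] >= 1  # operculum/midline side carried EGF input

    def test_transient_rho_pattern_retracts(self):
        """The early broad Rho/dpERK domain (the transient two-ring stage)
        is wider than the final pre-extinction pattern."""
        grid = HexGrid(*eggshell.DEFAULT_GRID)
        params = eggshell.WildtypeParams()
        model = eggshell.mechanistic_model()
        fields = eggshell.preset_scenario("WT").build_fields(grid, params)
        epi = eggshell.build_epithelium(
            model, grid,
            {"early_EGF": fields["early_EGF"], "early_BMP": fields["early_BMP"]},
        )
        epi.step()
        epi.step()
        epi.fields["early_EGF"] = np.zeros(grid.shape, np.int8)
        epi.fields["early_BMP"] = np.zeros(grid.shape, np.int8)
        epi.fields["Grk"] = fields["Grk"]
        epi.fields["Dpp"] = fields["Dpp"]
        epi.phase = "pre"
        widths = []
        for _ in range(15):
            epi.step()
            widths.append(int((epi.fields["Rho"] >= 1).sum()))
        assert max(widths) > widths[-1] > 0

    def test_phenomenological_and_mechanistic_agree(self, wt):
        """Same roof footprint cell-for-cell; same floor footprint."""
        ph, outcome = eggshell.run_phenomenological()
        assert outcome.kind == "fixed_point"
        assert np.array_equal(ph.fields["Roof"] >= 1, wt.epi_pre.fields["Br"] >= 1)
        assert np.array_equal(ph.fields["Floor"] >= 1, wt.epi_post.fields["Rho"] == 2)
        # operculum lies within the broad pre-extinction Rho/EGF domain
        assert (
            (ph.fields["Operculum"] >= 1) & ~(wt.epi_pre.fields["Rho"] >= 1)
        ).sum() == 0

    def test_census_robust_to_grid_scaling(self, wt, fates):
        """Scaling both dimensions x1.5 preserves the region census and the
        qualitative pattern relations."""
        big = HexGrid(36, 60)
        rm = eggshell.region_map(big)
        assert len(rm) == 12
        res = eggshell.run_scenario("WT", grid=big)
        _, summary = eggshell.classify_pattern(res.epi_post, fates)
        assert summary["n_roof_patches"] == 2
        assert summary["floor_all_touch_roof"]
        assert summary["floor_max_floor_neighbors"] <= 2
        assert np.array_equal(res.epi_pre.fields["Br"], res.epi_post.fields["Br"])


class TestMutants:
    def test_aos_lof_keeps_br_but_blocks_dperk_retraction(self, wt, scenario):
        res = scenario("Aos_LOF")
        assert np.array_equal(res.epi_post.fields["Br"], wt.epi_post.fields["Br"])
        # without Aos the high-dpERK domain stays one connected block
        blobs_wt = eggshell._components_of(wt.epi_post.fields["dpERK"] == 2, wt.epi_post.grid)
        blobs = eggshell._components_of(res.epi_post.fields["dpERK"] == 2, res.epi_post.grid)
        assert len(blobs_wt) == 2 and len(blobs) == 1

    def test_aos_gof_has_no_effect(self, wt, scenario):
        """The model cannot capture aos overexpression (a single Aos level):
        the mutant reproduces the wild type exactly — a documented failure
        that must be preserved, not patched."""
        res = scenario("Aos_GOF")
        assert np.array_equal(res.epi_post.fields["Br"], wt.epi_post.fields["Br"])
        assert np.array_equal(res.epi_post.fields["Rho"], wt.epi_post.fields["Rho"])

    def test_x_lof_eliminates_post_extinction_floor(self, scenario):
        res = scenario("X_LOF")
        assert int((res.epi_post.fields["Rho"] == 2).sum()) == 0
        assert int((res.epi_post.fields["Br"] >= 1).sum()) > 0  # roof remains

    def test_br_lof_clone_induces_rho_strictly_inside(self, wt, scenario):
        res = scenario("Br_LOF_clone")
        grid = res.epi_pre.grid
        mask = eggshell.roof_clone_mask(grid, eggshell.WildtypeParams())
        ectopic = (res.epi_pre.fields["Rho"] >= 1) & ~(wt.epi_pre.fields["Rho"] >= 1)
        assert ectopic.sum() > 0
        assert not (ectopic & ~mask).any()

    def test_br_lof_pattern_lost_after_extinction(self, scenario):
        res = scenario("Br_LOF")
        assert int((res.epi_pre.fields["Rho"] >= 1).sum()) > 0
        assert int((res.epi_post.fields["dpERK"] >= 1).sum()) == 0

    def test_gr1_dpp_gives_posterior_joined_horseshoe(self, wt, scenario):
        res = scenario("GR1_dpp")
        _, summary = eggshell.classify_pattern(res.epi_post)
        _, wt_summary = eggshell.classify_pattern(wt.epi_post)
        assert summary["n_roof_patches"] == 1  # joined over the midline
        assert summary["n_roof_cells"] > wt_summary["n_roof_cells"]
        # the joint lies posterior: some Br sits in rows that are Mid-positive in WT
        wt_mid = wt.epi_post.fields["Mid"]
        assert ((res.epi_post.fields["Br"] >= 1) & (wt_mid == 1)).any()

    def test_cy2_dpp_lacks_br_entirely(self, scenario):
        """Strong late dpp abolishes Br in the simulation; the experimental
        thin residual band is a known model failure kept as-is."""
        res = scenario("CY2_dpp")
        assert int((res.epi_post.fields["Br"] >= 1).sum()) == 0

    def test_tub_grk_abolishes_br(self, scenario):
        res = scenario("tub_grk")
        assert int((res.epi_post.fields["Br"] >= 1).sum()) == 0

    def test_pnt_lof_fuses_roof_over_midline(self, scenario):
        res = scenario("Pnt_LOF")
        _, summary = eggshell.classify_pattern(res.epi_post)
        assert summary["n_roof_patches"] == 1

    def test_dperk_gof_removes_roof_and_rings_the_anterior(self, scenario):
        res = scenario("dpERK_GOF")
        assert int((res.epi_post.fields["Br"] >= 1).sum()) == 0
        rho = res.epi_post.fields["Rho"] >= 1
        assert all(rho[:, c].any() for c in range(rho.shape[1]))  # full circumference

    def test_mid_clones_shift_the_competence_border(self, wt, scenario):
        _, wt_summary = eggshell.classify_pattern(wt.epi_post)
        lof = scenario("Mid_LOF_clone")
        gof = scenario("Mid_GOF_clone")
        _, lof_summary = eggshell.classify_pattern(lof.epi_post)
        _, gof_summary = eggshell.classify_pattern(gof.epi_post)
        assert lof_summary["n_roof_cells"] > wt_summary["n_roof_cells"]
        assert gof_summary["n_roof_cells"] < wt_summary["n_roof_cells"]

    def test_bmp_lof_timing_reconciles_conflicting_results(self, wt, scenario):
        """Early pathway loss shrinks the roof (competence lost posteriorly);
        late-only loss instead extends Br into the former Dpp band."""
        _, wt_summary = eggshell.classify_pattern(wt.epi_post)
        early = scenario("BMP_LOF_early")
        late = scenario("BMP_LOF_late")
        _, early_summary = eggshell.classify_pattern(early.epi_post)
        _, late_summary = eggshell.classify_pattern(late.epi_post)
        assert early_summary["n_roof_cells"] < wt_summary["n_roof_cells"]
        assert late_summary["n_roof_cells"] > wt_summary["n_roof_cells"]
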