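"""Tests for normalization, field combination, DVHs, and plan summaries."""

import numpy as np
import pytest

from protonplan.dosimetry import (
    DoseGrid,
    DosimetryError,
    OrganDoseStats,
    PlanSummary,
    StructureMask,
    combine_fields,
    compare_summaries,
    cumulative_dvh,
    dose_summary,
    load_reference_plan_summaries,
    normalize_to_ctv_mean,
    read_dose_grid,
    read_structure_mask,
    write_dose_grid,
    write_structure_mask,
)


def small_grid(values):
    values = np.asarray(values, dtype=float)
    return DoseGrid(values, spacing=(1.0, 1.0, 1.0))


def full_mask(shape, label="ctv"):
    return StructureMask(np.ones(shape, dtype=bool), spacing=(1.0, 1.0, 1.0), label=label)


class TestNormalization:
    def test_scales_to_prescription(self):
        grid = small_grid(np.full((4, 4, 4), 38.0))
        out = normalize_to_ctv_mean(grid, full_mask((4, 4, 4)), prescription=76.0)
        assert out.values.mean() == pytest.approx(76.0, rel=1e-12)
        assert np.allclose(out.values, 2 * grid.values)

    def test_idempotent(self):
        grid = small_grid(np.random.default_rng(0).uniform(1, 80, (5, 5, 5)))
        ctv = full_mask((5, 5, 5))
        once = normalize_to_ctv_mean(grid, ctv)
        twice = normalize_to_ctv_mean(once, ctv)
        assert np.allclose(once.values, twice.values)

    def test_scale_equivariant(self):
        grid = small_grid(np.random.default_rng(1).uniform(1, 80, (5, 5, 5)))
        ctv = full_mask((5, 5, 5))
        a = normalize_to_ctv_mean(grid, ctv)
        b = normalize_to_ctv_mean(grid.scaled(7.3), ctv)
        assert np.allclose(a.values, b.values)

    def test_empty_or_zero_ctv_rejected(self):
        grid = small_grid(np.ones((3, 3, 3)))
        empty = StructureMask(np.zeros((3, 3, 3), bool), spacing=(1, 1, 1), label="ctv")
        with pytest.raises(DosimetryError):
            normalize_to_ctv_mean(grid, empty)
        zero = small_grid(np.zeros((3, 3, 3)))
        with pytest.raises(DosimetryError):
            normalize_to_ctv_mean(zero, full_mask((3, 3, 3)))


class TestCombineFields:
    def test_two_fields_reach_total_prescription(self, default_plan):
        combined = combine_fields(default_plan.fields, default_plan.ctv)
        ctv_doses = combined.values[default_plan.ctv.values]
        assert ctv_doses.mean() == pytest.approx(69.0, rel=1e-12)

    def test_single_field(self, default_plan):
        combined = combine_fields(default_plan.fields[:1], default_plan.ctv)
        assert combined.values[default_plan.ctv.values].mean() == pytest.approx(34.5, rel=1e-12)

    def test_order_invariant(self, default_plan):
        a = combine_fields(default_plan.fields, default_plan.ctv)
        b = combine_fields(default_plan.fields[::-1], default_plan.ctv)
        assert np.allclose(a.values, b.values)

    def test_geometry_mismatch_rejected(self):
        f1 = small_grid(np.ones((3, 3, 3)))
        f2 = small_grid(np.ones((4, 3, 3)))
        with pytest.raises(DosimetryError):
            combine_fields([f1, f2], full_mask((3, 3, 3)))

    def test_no_fields_rejected(self, default_plan):
        with pytest.raises(DosimetryError):
            combine_fields([], default_plan.ctv)


class TestDVH:
    def test_uniform_dose_is_step_function(self):
        grid = small_grid(np.full((3, 3, 3), 20.0))
        curve = cumulative_dvh(grid, full_mask((3, 3, 3)), bin_width=5.0)
        expected = [100.0 if edge <= 20.0 else 0.0 for edge in curve.dose_edges]
        assert list(curve.volume_fraction) == expected
        assert curve.volume_fraction[-1] == 0.0

    def test_two_voxel_enumeration(self):
        values = np.zeros((2, 1, 1))
        values[0], values[1] = 10.0, 30.0
        grid = small_grid(values)
        curve = cumulative_dvh(grid, full_mask((2, 1, 1)), bin_width=10.0)
        assert list(curve.dose_edges) == [0.0, 10.0, 20.0, 30.0, 40.0]
        assert list(curve.volume_fraction) == [100.0, 100.0, 50.0, 50.0, 0.0]

    def test_starts_at_hundred_and_monotone(self, default_plan):
        combined = combine_fields(default_plan.fields, default_plan.ctv)
        for mask in default_plan.masks.values():
            curve = cumulative_dvh(combined, mask)
            assert curve.volume_fraction[0] == 100.0
            assert np.all(np.diff(curve.volume_fraction) <= 0)
            assert curve.volume_fraction[-1] == 0.0

    def test_mean_recovered_from_curve(self, rng):
        """Riemann sum of the survival curve equals the voxel mean within a bin."""
        values = rng.uniform(0, 60, (8, 8, 8))
        grid = small_grid(values)
        bin_width = 0.5
        curve = cumulative_dvh(grid, full_mask((8, 8, 8)), bin_width=bin_width)
        riemann_mean = bin_width * np.sum(curve.volume_fraction[1:]) / 100.0
        assert abs(riemann_mean - values.mean()) <= bin_width

    def test_volume_at_dose_lookup(self):
        grid = small_grid(np.full((2, 2, 2), 10.0))
        curve = cumulative_dvh(grid, full_mask((2, 2, 2)), bin_width=1.0)
        assert curve.volume_at_dose(0.0) == 100.0
        assert curve.volume_at_dose(10.5) == 0.0

    def test_empty_mask_and_bad_bin_rejected(self):
        grid = small_grid(np.ones((2, 2, 2)))
        with pytest.raises(DosimetryError):
            cumulative_dvh(grid, StructureMask(np.zeros((2, 2, 2), bool), spacing=(1, 1, 1)))
        with pytest.raises(DosimetryError):
            cumulative_dvh(grid, full_mask((2, 2, 2)), bin_width=0.0)


class TestSummary:
    def test_uniform_grid(self):
        grid = small_grid(np.full((3, 3, 3), 5.0))
        masks = [full_mask((3, 3, 3), "bladder"), full_mask((3, 3, 3), "rectum")]
        summary = dose_summary(grid, masks)
        for stats in summary.organs.values():
            assert stats == OrganDoseStats(5.0, 5.0)

    def test_empty_mask_reported_not_dropped(self):
        grid = small_grid(np.ones((3, 3, 3)))
        empty = StructureMask(np.zeros((3, 3, 3), bool), spacing=(1, 1, 1), label="seminal")
        summary = dose_summary(grid, [full_mask((3, 3, 3)), empty])
        assert "seminal" in summary.errors
        assert "seminal" not in summary.organs

    def test_mean_not_above_max(self, default_plan):
        combined = combine_fields(default_plan.fields, default_plan.ctv)
        summary = dose_summary(combined, default_plan.masks.values())
        for stats in summary.organs.values():
            assert stats.mean <= stats.max


class TestReferenceSummaries:
    def test_ctv_normalization_of_published_cohort(self):
        plans = load_reference_plan_summaries()
        assert plans["SOC"].organs["CTV"].mean == 75.90
        assert plans["MLC-only"].organs["CTV"].mean == 75.90

    def test_bladder_mean_delta_soc_vs_mlc_rc(self):
        plans = load_reference_plan_summaries()
        deltas = compare_summaries(plans["SOC"], plans["MLC+RC"])
        assert deltas["Bladder"].mean == pytest.approx(-0.69)  # 12.18 - 12.87

    def test_rectum_mean_delta_soc_vs_mlc_only(self):
        plans = load_reference_plan_summaries()
        deltas = compare_summaries(plans["SOC"], plans["MLC-only"])
        assert deltas["Rectum"].mean == pytest.approx(0.03)  # 16.76 - 16.73

    def test_identical_summaries_zero_deltas(self):
        plans = load_reference_plan_summaries()
        deltas = compare_summaries(plans["SOC"], plans["SOC"])
        assert all(d.max == 0 and d.mean == 0 for d in deltas.values())

    def test_organ_set_mismatch_rejected(self):
        plans = load_reference_plan_summaries()
        truncated = PlanSummary("partial", dict(list(plans["SOC"].organs.items())[:3]))
        with pytest.raises(DosimetryError):
            compare_summaries(plans["SOC"], truncated)


class TestNRRDRoundTrip:
    def test_dose_grid(self, tmp_path):
        grid = DoseGrid(
            np.random.default_rng(3).uniform(0, 70, (6, 5, 4)),
            spacing=(0.5, 0.25, 1.0),
            origin=(1.0, -2.0, 3.0),
        )
        path = tmp_path / "dose.nrrd"
        write_dose_grid(grid, path)
        back = read_dose_grid(path)
        assert np.allclose(back.values, grid.values)
        assert back.spacing == pytest.approx(grid.spacing)
        assert back.origin == pytest.approx(grid.origin)

    def test_structure_mask(self, tmp_path):
        mask = StructureMask(
            np.random.default_rng(4).uniform(size=(6, 5, 4)) > 0.5,
            spacing=(0.5, 0.5, 0.5),
            label="ctv",
        )
        path = tmp_path / "mask.nrrd"
        write_structure_mask(mask, path)
        back = read_structure_mask(path, label="ctv")
        assert np.array_equal(back.values, mask.values)
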