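"""Masked measurement, well/condition aggregation and plate-reader modes."""

import numpy as np
import pandas as pd
import pytest

import mitoscreen as ms
from mitoscreen import (BackgroundModel, CellMeasurement, aggregate_condition,
                        measure_cells, normalize_platereader,
                        percent_reduction, percent_vs_control,
                        relative_viability, summarize_well)
from mitoscreen.segment import SegmentationResult

NO_BG = BackgroundModel("none", curvature=None)


def tiny_field_and_seg():
    """Hand-built 6x6 field: one cell, 4-pixel mask of values {3,5,7,9}."""
    mros = np.zeros((6, 6))
    mros[1, 1], mros[1, 2], mros[2, 1], mros[2, 2] = 3.0, 5.0, 7.0, 9.0
    mros[4, 4] = 100.0           # outside the mask: must be excluded
    mito = np.full((6, 6), 2.0)
    nuclei = np.zeros((6, 6))
    field = ms.FieldImage("B02", 0, nuclei, mito, mros, pixel_size_um=0.6)
    cell_labels = np.ones((6, 6), dtype=np.int32)
    masks = np.zeros((6, 6), dtype=np.int32)
    masks[1:3, 1:3] = 1
    seg = SegmentationResult(nucleus_labels=cell_labels,
                             cell_labels=cell_labels, mito_mask_labels=masks)
    return field, seg


class TestMeasureCells:
    def test_hand_summation_on_fixture(self):
        field, seg = tiny_field_and_seg()
        (cell,) = measure_cells(field, seg, NO_BG)
        assert cell.mros_signal == 24.0          # 3+5+7+9, outside excluded
        assert cell.mito_rfu == 2.0
        assert cell.mito_area_um2 == pytest.approx(4 * 0.36)

    def test_empty_mask_measures_zero(self):
        field, seg = tiny_field_and_seg()
        empty = SegmentationResult(seg.nucleus_labels, seg.cell_labels,
                                   np.zeros((6, 6), dtype=np.int32))
        (cell,) = measure_cells(field, empty, NO_BG)
        assert (cell.mros_signal, cell.mito_rfu, cell.mito_area_um2) == \
            (0.0, 0.0, 0.0)

    def test_area_in_um2(self):
        mask = np.zeros((10, 10), dtype=np.int32)
        mask[2:7, 2:7] = 1                        # 25 px
        seg = SegmentationResult(mask, mask, mask)
        field = ms.FieldImage("A01", 0, np.zeros((10, 10)),
                              np.ones((10, 10)), np.ones((10, 10)),
                              pixel_size_um=0.6)
        (cell,) = measure_cells(field, seg, NO_BG)
        assert cell.mito_area_um2 == pytest.approx(9.0)

    def test_shape_mismatch_rejected(self):
        field, _ = tiny_field_and_seg()
        bad = SegmentationResult(np.zeros((4, 4), dtype=np.int32),
                                 np.zeros((4, 4), dtype=np.int32),
                                 np.zeros((4, 4), dtype=np.int32))
        with pytest.raises(ValueError):
            measure_cells(field, bad, NO_BG)

    def test_linearity_in_intensity(self, default_field):
        img, _ = default_field
        seg = ms.segment_field(img)
        base = measure_cells(img, seg, NO_BG)
        scaled_img = ms.FieldImage(img.well_id, img.field_index,
                                   img.nuclei_ch, img.mito_ch,
                                   img.mros_ch * 3.0, img.pixel_size_um)
        scaled = measure_cells(scaled_img, seg, NO_BG)
        for b, s in zip(base, scaled):
            assert s.mros_signal == pytest.approx(3.0 * b.mros_signal,
                                                  rel=1e-12)


class TestWellAndCondition:
    def cell(self, signal, well="B02", fi=0, cid=1):
        return CellMeasurement(well, fi, cid, signal, 10.0, 5.0)

    def test_per_cell_mean(self):
        cells = [self.cell(10.0, cid=1), self.cell(20.0, cid=2),
                 self.cell(30.0, cid=3)]
        assert summarize_well(cells).mean_mros_per_cell == 20.0

    def test_single_cell_summary_equals_measurement(self):
        (summary,) = [summarize_well([self.cell(42.0)])]
        assert summary.mean_mros_per_cell == 42.0
        assert summary.n_cells == 1

    def test_field_partition_invariance(self):
        pooled = [self.cell(v, fi=0, cid=i) for i, v in enumerate((1., 2., 3., 4.))]
        split = [self.cell(v, fi=i % 2, cid=i) for i, v in enumerate((1., 2., 3., 4.))]
        assert summarize_well(pooled) == summarize_well(split)

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            summarize_well([])

    def test_percent_conventions(self):
        assert percent_vs_control(1.477, 1.0) == pytest.approx(47.7)
        assert percent_vs_control(5.0, 5.0) == 0.0
        assert percent_reduction(0.6378, 1.0) == pytest.approx(36.22)
        with pytest.raises(ZeroDivisionError):
            percent_vs_control(1.0, 0.0)

    def test_aggregate_condition_stats(self):
        wells = pd.DataFrame([
            {"condition": "basal", "mean_mros_per_cell": 10.0,
             "mean_mito_rfu": 1.0, "mean_mito_area_um2": 5.0, "n_cells": 50},
            {"condition": "basal", "mean_mros_per_cell": 12.0,
             "mean_mito_rfu": 1.2, "mean_mito_area_um2": 5.5, "n_cells": 40},
            {"condition": "oxldl", "mean_mros_per_cell": 16.0,
             "mean_mito_rfu": 1.1, "mean_mito_area_um2": 5.2, "n_cells": 45},
            {"condition": "oxldl", "mean_mros_per_cell": 17.0,
             "mean_mito_rfu": 1.0, "mean_mito_area_um2": 5.1, "n_cells": 44},
        ])
        out = aggregate_condition(wells, "basal").set_index("condition")
        assert out.loc["basal", "percent_vs_control"] == 0.0
        assert out.loc["oxldl", "percent_vs_control"] == pytest.approx(50.0)
        assert out.loc["basal", "mean_mros_per_cell_sd"] == pytest.approx(
            np.std([10.0, 12.0], ddof=1))
        assert out.loc["basal", "mean_mros_per_cell_sem"] == pytest.approx(
            np.std([10.0, 12.0], ddof=1) / np.sqrt(2))
        assert out.loc["oxldl", "n_wells"] == 2

    def test_missing_control_rejected(self):
        wells = pd.DataFrame([{"condition": "a", "mean_mros_per_cell": 1.0,
                               "mean_mito_rfu": 1.0,
                               "mean_mito_area_um2": 1.0, "n_cells": 5}])
        with pytest.raises(ValueError, match="control"):
            aggregate_condition(wells, "zz")


class TestPlateReader:
    def records(self):
        return pd.DataFrame([
            {"well_id": "A01", "raw_rfu": 500.0, "protein_ug": 80.0},
            {"well_id": "A02", "raw_rfu": 100.0, "protein_ug": 50.0},
            {"well_id": "H11", "raw_rfu": 90.0, "protein_ug": np.nan},
            {"well_id": "H12", "raw_rfu": 110.0, "protein_ug": np.nan},
        ])

    def test_normalization_arithmetic(self):
        out = normalize_platereader(self.records(), ["H11", "H12"])
        out = out.set_index("well_id")
        assert out.loc["A01", "normalized_rfu_per_ug"] == pytest.approx(5.0)
        assert out.loc["A02", "normalized_rfu_per_ug"] == pytest.approx(0.0)

    def test_missing_protein_rejected(self):
        rec = self.records()
        rec.loc[rec["well_id"] == "A01", "protein_ug"] = np.nan
        with pytest.raises(ValueError, match="protein"):
            normalize_platereader(rec, ["H11", "H12"])

    def test_requires_blank_wells(self):
        with pytest.raises(ValueError, match="blank"):
            normalize_platereader(self.records(), ["G01"])

    def test_group_difference_on_reported_scale(self):
        # condition means of 6.35 and 1.61 RFU/ug differ by 4.74 RFU/ug
        assert 6.35 - 1.61 == pytest.approx(4.74)


class TestViability:
    def test_vehicle_is_100_percent(self):
        rec = pd.DataFrame([
            {"well_id": "A01", "condition": "vehicle", "luminescence": 5000.0},
            {"well_id": "A02", "condition": "vehicle", "luminescence": 5000.0},
            {"well_id": "B01", "condition": "drug", "luminescence": 2500.0},
        ])
        out = relative_viability(rec, ["A01", "A02"]).set_index("condition")
        assert out.loc["vehicle", "viability_percent"] == 100.0
        assert out.loc["drug", "viability_percent"] == 50.0

    def test_reduction_convention(self):
        rec = pd.DataFrame([
            {"well_id": "A01", "condition": "vehicle", "luminescence": 1000.0},
            {"well_id": "B01", "condition": "colchicine_1uM",
             "luminescence": 237.0},
        ])
        out = relative_viability(rec, ["A01"]).set_index("condition")
        v = out.loc["colchicine_1uM", "viability_percent"]
        assert v == pytest.approx(23.7)
        assert 100.0 - v == pytest.approx(76.3)

    def test_nonpositive_vehicle_rejected(self):
        rec = pd.DataFrame([
            {"well_id": "A01", "condition": "vehicle", "luminescence": 0.0}])
        with pytest.raises(ValueError, match="vehicle"):
            relative_viability(rec, ["A01"])


class TestMaskingSpecificity:
    def test_nonspecific_signal_changes_totals_not_masked_means(self):
        # cytoplasmic (non-mitochondrial) reporter signal inflates the
        # whole-field total but leaves mitochondria-masked per-cell means
        # nearly unchanged: the plate-reader vs confocal specificity gap
        blank, _ = ms.simulate_field(0, seed=8)
        blank_total = ms.whole_field_total(blank)
        means, totals = {}, {}
        for f in (0.0, 0.5):
            img, truth = ms.simulate_field(12, s=1.0,
                                           nonspecific_fraction=f, seed=8)
            seg = ms.segment_field(img)
            cells = measure_cells(img, seg, NO_BG)
            means[f] = np.mean([c.mros_signal for c in cells])
            # plate-reader emulation: whole-field sum minus the empty-well
            # (cell-free) background total
            totals[f] = ms.whole_field_total(img) - blank_total
        assert totals[0.5] / totals[0.0] > 1.5
        assert abs(means[0.5] / means[0.0] - 1) < 0.05
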