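"""Per-cell, per-well and per-condition quantification, plus plate-reader
and viability normalizations.

The imaging readouts per cell are: the background-corrected superoxide
reporter signal summed over the cell's mitochondrial mask (RFU; non-masked
fluorescence is excluded), the mean mitochondrial-channel intensity over the
mask (membrane-potential proxy, RFU — a mean so that it is independent of
mask area), and the mask area in um^2.  Wells average per-cell values over
all fields; conditions average replicate wells and are expressed as percent
of the designated control: ``(condition mean / control mean - 1) x 100`` for
increases, ``(1 - ratio) x 100`` for reductions.

Plate-reader mode normalizes raw well fluorescence to protein content,
``(raw - mean blank) / protein_ug``; viability mode expresses luminescence
as percent of the vehicle control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .background import BackgroundModel
from .model_io import FieldImage
from .segment import SegmentationResult

__all__ = [
    "CellMeasurement", "WellSummary",
    "measure_cells", "summarize_well", "aggregate_condition",
    "percent_vs_control", "percent_reduction", "whole_field_total",
    "normalize_platereader", "relative_viability",
]


@dataclass(frozen=True)
class CellMeasurement:
    """Masked readouts of one retained cell."""

    well_id: str
    field_index: int
    cell_id: int
    mros_signal: float     # background-corrected sum over the mito mask, RFU
    mito_rfu: float        # mean mito-channel intensity over the mask, RFU
    mito_area_um2: float   # mask pixel count x pixel_size_um^2


@dataclass(frozen=True)
class WellSummary:
    """Per-cell means of one well's measurements."""

    well_id: str
    mean_mros_per_cell: float
    mean_mito_rfu: float
    mean_mito_area_um2: float
    n_cells: int


def measure_cells(field: FieldImage, seg: SegmentationResult,
                  bg: BackgroundModel = BackgroundModel("none", curvature=None),
                  correct_mito_channel: bool = False) -> List[CellMeasurement]:
    """Measure every retained cell of a field.

    The background model is applied to the superoxide channel before the
    masked sum; signal strictly excludes pixels outside the cell's
    mitochondrial mask.  Cells with an empty mask yield (0, 0, 0).
    """
    if seg.cell_labels.shape != field.shape:
        raise ValueError("segmentation does not match field shape")
    mros = bg.apply(field.mros_ch)
    mito = bg.apply(field.mito_ch) if correct_mito_channel else field.mito_ch
    px_area = field.pixel_size_um ** 2

    labels = seg.labels
    out: List[CellMeasurement] = []
    mask_labels = seg.mito_mask_labels
    for lab in labels:
        mask = mask_labels == lab
        n_px = int(mask.sum())
        if n_px == 0:
            out.append(CellMeasurement(field.well_id, field.field_index,
                                       int(lab), 0.0, 0.0, 0.0))
            continue
        out.append(CellMeasurement(
            well_id=field.well_id, field_index=field.field_index,
            cell_id=int(lab),
            mros_signal=float(mros[mask].sum()),
            mito_rfu=float(mito[mask].mean()),
            mito_area_um2=n_px * px_area))
    return out


def summarize_well(cells: Sequence[CellMeasurement]) -> WellSummary:
    """Average per-cell measurements over all fields of one well.

    The well metric is the per-cell mean of the masked sums (total signal
    across cells divided by the number of cells analysed), so pooling the
    same cells into fewer fields changes nothing.
    """
    if not cells:
        raise ValueError("summarize_well requires >= 1 cell "
                         "(no-cells wells are flagged upstream)")
    well_ids = {c.well_id for c in cells}
    if len(well_ids) != 1:
        raise ValueError(f"cells from multiple wells: {sorted(well_ids)}")
    return WellSummary(
        well_id=cells[0].well_id,
        mean_mros_per_cell=float(np.mean([c.mros_signal for c in cells])),
        mean_mito_rfu=float(np.mean([c.mito_rfu for c in cells])),
        mean_mito_area_um2=float(np.mean([c.mito_area_um2 for c in cells])),
        n_cells=len(cells))


def percent_vs_control(value: float, control: float) -> float:
    """Percent increase over control: ``(value / control - 1) x 100``."""
    if control == 0:
        raise ZeroDivisionError("control mean is 0: percent-of-control "
                                "normalization undefined")
    return (value / control - 1.0) * 100.0


def percent_reduction(value: float, control: float) -> float:
    """Percent reduction vs control: ``(1 - value / control) x 100``."""
    return -percent_vs_control(value, control)


def aggregate_condition(wells: pd.DataFrame,
                        control_condition: Optional[str]) -> pd.DataFrame:
    """Replicate-average well summaries per condition.

    ``wells`` must carry columns ``condition``, ``mean_mros_per_cell``,
    ``mean_mito_rfu``, ``mean_mito_area_um2``, ``n_cells``.  Returns one row
    per condition with mean, sd and sem over replicate wells of each metric
    and ``percent_vs_control`` of the superoxide readout (0 for the control
    by construction).
    """
    if wells is None or len(wells) == 0:
        return pd.DataFrame()
    metrics = ["mean_mros_per_cell", "mean_mito_rfu", "mean_mito_area_um2"]
    rows = []
    for cond, grp in wells.groupby("condition", sort=True):
        row = {"condition": cond, "n_wells": len(grp),
               "n_cells": int(grp["n_cells"].sum())}
        for m in metrics:
            vals = grp[m].to_numpy(dtype=float)
            row[m] = float(vals.mean())
            row[m + "_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            row[m + "_sem"] = (row[m + "_sd"] / np.sqrt(len(vals))
                               if len(vals) > 1 else 0.0)
        rows.append(row)
    df = pd.DataFrame(rows)
    if control_condition is not None:
        ctrl = df.loc[df["condition"] == control_condition,
                      "mean_mros_per_cell"]
        if len(ctrl) == 0:
            raise ValueError(f"control condition {control_condition!r} has "
                             "no valid wells")
        df["percent_vs_control"] = [
            percent_vs_control(v, float(ctrl.iloc[0]))
            for v in df["mean_mros_per_cell"]]
    return df


def whole_field_total(field: FieldImage) -> float:
    """Plate-reader emulation: total raw superoxide-channel signal of a field
    (no masking, no per-pixel correction)."""
    return float(field.mros_ch.sum())


def normalize_platereader(records: pd.DataFrame,
                          blank_wells: Iterable[str]) -> pd.DataFrame:
    """Blank-subtract and protein-normalize plate-reader fluorescence.

    ``records`` needs columns ``well_id``, ``raw_rfu``, ``protein_ug``.
    Blank wells (cell-free) define the background mean;
    ``normalized = (raw_rfu - blank_mean) / protein_ug`` in RFU/ug.
    """
    blank_wells = set(blank_wells)
    df = records.copy()
    blanks = df[df["well_id"].isin(blank_wells)]
    if len(blanks) == 0:
        raise ValueError("no blank wells found in the records")
    blank_mean = float(blanks["raw_rfu"].mean())
    df = df[~df["well_id"].isin(blank_wells)].copy()
    if df["protein_ug"].isna().any():
        bad = df.loc[df["protein_ug"].isna(), "well_id"].tolist()
        raise ValueError(f"missing protein values for wells {bad}")
    if (df["protein_ug"] <= 0).any():
        bad = df.loc[df["protein_ug"] <= 0, "well_id"].tolist()
        raise ValueError(f"protein_ug must be > 0 (wells {bad})")
    df["blank_mean_rfu"] = blank_mean
    df["normalized_rfu_per_ug"] = ((df["raw_rfu"] - blank_mean)
                                   / df["protein_ug"])
    return df


def relative_viability(records: pd.DataFrame,
                       vehicle_wells: Iterable[str]) -> pd.DataFrame:
    """Luminescence viability as percent of the vehicle control.

    ``records`` needs columns ``well_id``, ``condition``, ``luminescence``.
    Returns per-condition mean viability,
    ``100 x condition mean / vehicle mean``.
    """
    vehicle_wells = set(vehicle_wells)
    veh = records[records["well_id"].isin(vehicle_wells)]
    if len(veh) == 0:
        raise ValueError("no vehicle wells found in the records")
    veh_mean = float(veh["luminescence"].mean())
    if veh_mean <= 0:
        raise ValueError("vehicle-control mean must be > 0")
    rows = []
    for cond, grp in records.groupby("condition", sort=True):
        vals = grp["luminescence"].to_numpy(dtype=float)
        rows.append({"condition": cond, "n": len(vals),
                     "viability_percent": 100.0 * vals.mean() / veh_mean})
    return pd.DataFrame(rows)
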