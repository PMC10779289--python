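"""Core data model, plate-layout parsing, image I/O and pipeline orchestration.

A screening run is described by a :class:`PlateLayout` (96-well plate, each
well assigned one condition and a role), a set of imaged fields per well
(:class:`FieldImage`: three co-registered 2-D channels — nuclei, mitochondria,
superoxide reporter), and analysis parameters (:class:`PipelineParams`).

Conventions
-----------
* Channel order in 3-plane TIFFs is fixed as (nuclei, mito, mros), matching
  the excitation-laser listing order 405 / 640 / 561 nm.
* Pixel indices are 0-based, row-major; areas are reported in um^2 via
  ``pixel_size_um**2`` (default 0.6 um/px).
* Fields are single-plane 2-D images; any z dimension must be max-projected
  upstream.
* Field files are named ``<well>_f<field>.tif`` (e.g. ``B07_f00.tif``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .background import DEFAULT_CURVATURE, BackgroundModel

logger = logging.getLogger(__name__)

__all__ = [
    "FieldImage", "WellSpec", "PlateLayout", "PipelineParams",
    "PipelineResult", "LayoutError", "FormatError",
    "load_layout", "save_layout", "demo_layout",
    "read_field", "write_field", "load_plate_images", "run_pipeline",
]

WELL_RE = re.compile(r"^[A-H](0[1-9]|1[0-2])$")
ROLES = frozenset({"negative_control", "positive_control", "vehicle_control",
                   "treatment", "background_well", "empty"})
DEFAULT_PIXEL_SIZE_UM = 0.6


class LayoutError(ValueError):
    """Invalid plate-layout configuration."""


class FormatError(ValueError):
    """Invalid image file format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldImage:
    """One imaged field: three co-registered channel rasters.

    Channels: ``nuclei_ch`` (nuclear dye, 405 nm excitation), ``mito_ch``
    (mitochondrial dye, 640 nm), ``mros_ch`` (superoxide reporter, 561 nm).
    Integer inputs are promoted to float64 without rescaling.
    """

    well_id: str
    field_index: int
    nuclei_ch: np.ndarray
    mito_ch: np.ndarray
    mros_ch: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        for name in ("nuclei_ch", "mito_ch", "mros_ch"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.ndim != 2:
                raise FormatError(f"{name} must be 2-D")
            if not np.all(np.isfinite(arr)) or arr.min() < 0:
                raise FormatError(f"{name} must be finite and non-negative")
            object.__setattr__(self, name, arr)
        if self.nuclei_ch.shape != self.mito_ch.shape or \
                self.nuclei_ch.shape != self.mros_ch.shape:
            raise FormatError("channel rasters must share identical shape")
        if self.field_index < 0:
            raise ValueError("field_index must be >= 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple:
        return self.nuclei_ch.shape


@dataclass(frozen=True)
class WellSpec:
    """Assignment of one well: condition label, role, optional drug dose (nM).

    A dose is only meaningful on drug-treatment wells; ``background_well``
    wells contain no cells and feed the background-well correction only.
    """

    well_id: str
    condition: str
    role: str = "treatment"
    dose_nM: Optional[float] = None

    def __post_init__(self) -> None:
        if not WELL_RE.match(self.well_id):
            raise LayoutError(
                f"invalid 96-well coordinate {self.well_id!r} "
                "(expected A01..H12)")
        if self.role not in ROLES:
            raise LayoutError(f"unknown role {self.role!r} for well "
                              f"{self.well_id}; allowed: {sorted(ROLES)}")
        if self.dose_nM is not None:
            if self.role != "treatment":
                raise LayoutError(
                    f"dose on non-treatment well {self.well_id} "
                    f"(role {self.role!r})")
            if not self.dose_nM > 0:
                raise LayoutError(f"dose must be > 0 (well {self.well_id})")


@dataclass(frozen=True)
class PlateLayout:
    """Validated plate layout: well specs plus imaging metadata.

    ``fields_per_well`` is configurable; published runs of this assay used
    10-20 fields of view per well, and 10 is the default here.
    """

    wells: tuple
    fields_per_well: int = 10
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple(self.wells))
        seen = set()
        for w in self.wells:
            if w.well_id in seen:
                raise LayoutError(f"duplicate well assignment: {w.well_id}")
            seen.add(w.well_id)
        if self.fields_per_well < 1:
            raise LayoutError("fields_per_well must be >= 1")
        if not self.pixel_size_um > 0:
            raise LayoutError("pixel_size_um must be > 0")

    @property
    def replicate_groups(self) -> Dict[str, List[str]]:
        """Mapping condition -> replicate well ids (cell-bearing wells)."""
        groups: Dict[str, List[str]] = {}
        for w in self.wells:
            if w.role in ("background_well", "empty"):
                continue
            groups.setdefault(w.condition, []).append(w.well_id)
        return groups

    @property
    def background_wells(self) -> List[str]:
        return [w.well_id for w in self.wells if w.role == "background_well"]

    def well(self, well_id: str) -> WellSpec:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(well_id)

    def wells_with_role(self, role: str) -> List[str]:
        return [w.well_id for w in self.wells if w.role == role]

    def condition_of(self, well_id: str) -> str:
        return self.well(well_id).condition


# ---------------------------------------------------------------------------
# layout I/O (YAML)
# ---------------------------------------------------------------------------

def load_layout(path: Union[str, Path]) -> PlateLayout:
    """Load and validate a plate layout from a YAML config file.

    Expected structure::

        fields_per_well: 10
        pixel_size_um: 0.6
        wells:
          - {well: B02, condition: basal, role: negative_control}
          - {well: B03, condition: oxldl, role: treatment}
          - {well: H12, condition: background, role: background_well}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "wells" not in raw:
        raise LayoutError(f"{path}: layout file must contain a 'wells' list")
    wells = []
    for entry in raw["wells"]:
        try:
            wells.append(WellSpec(
                well_id=str(entry["well"]),
                condition=str(entry["condition"]),
                role=str(entry.get("role", "treatment")),
                dose_nM=(None if entry.get("dose_nM") is None
                         else float(entry["dose_nM"])),
            ))
        except KeyError as exc:
            raise LayoutError(f"{path}: well entry missing key {exc}") from exc
    return PlateLayout(
        wells=tuple(wells),
        fields_per_well=int(raw.get("fields_per_well", 10)),
        pixel_size_um=float(raw.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)),
    )


def save_layout(layout: PlateLayout, path: Union[str, Path]) -> None:
    """Write a layout back to YAML (round-trips through :func:`load_layout`)."""
    doc = {
        "fields_per_well": layout.fields_per_well,
        "pixel_size_um": layout.pixel_size_um,
        "wells": [
            {k: v for k, v in (
                ("well", w.well_id), ("condition", w.condition),
                ("role", w.role), ("dose_nM", w.dose_nM)) if v is not None}
            for w in layout.wells
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def demo_layout() -> PlateLayout:
    """A 28-well demo plate: 7 conditions in triplicate, 2 background wells,
    5 unused (empty) wells — the shape of a small one-drug dose screen."""
    conditions = [
        ("basal", "negative_control", None),
        ("oxldl", "positive_control", None),
        ("oxldl+drug_1nM", "treatment", 1.0),
        ("oxldl+drug_10nM", "treatment", 10.0),
        ("oxldl+drug_100nM", "treatment", 100.0),
        ("oxldl+drug_1000nM", "treatment", 1000.0),
        ("oxldl+vehicle", "vehicle_control", None),
    ]
    rows = "BCD"
    wells = []
    for j, (cond, role, dose) in enumerate(conditions):
        for i, row in enumerate(rows):
            wells.append(WellSpec(f"{row}{j + 2:02d}", cond, role, dose))
    wells.append(WellSpec("G02", "background", "background_well"))
    wells.append(WellSpec("G03", "background", "background_well"))
    for j in range(5):
        wells.append(WellSpec(f"H{j + 2:02d}", "unused", "empty"))
    return PlateLayout(wells=tuple(wells))


# ---------------------------------------------------------------------------
# field image I/O (multi-page TIFF)
# ---------------------------------------------------------------------------

def field_filename(well_id: str, field_index: int) -> str:
    return f"{well_id}_f{field_index:02d}.tif"


def write_field(field_img: FieldImage, directory: Union[str, Path]) -> Path:
    """Write one field as a 3-plane TIFF (nuclei, mito, mros plane order).

    Values are stored as 64-bit float, so both integer camera data and
    simulated intensities survive the round trip bit-identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / field_filename(field_img.well_id, field_img.field_index)
    stack = np.stack([field_img.nuclei_ch, field_img.mito_ch,
                      field_img.mros_ch])
    tifffile.imwrite(path, stack, photometric="minisblack",
                     metadata={"pixel_size_um": field_img.pixel_size_um})
    return path


def read_field(path: Union[str, Path],
               well_id: Optional[str] = None,
               field_index: Optional[int] = None,
               pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> FieldImage:
    """Read a 3-plane TIFF field (plane order nuclei, mito, mros).

    ``well_id`` / ``field_index`` default to parsing the ``<well>_f<k>.tif``
    file name.  Raises :class:`FormatError` when the plane count is not 3 or
    plane shapes disagree.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        raise FormatError(f"{path}: expected 3 channel planes, found 1")
    if data.ndim != 3 or data.shape[0] != 3:
        raise FormatError(
            f"{path}: expected 3 channel planes, found shape {data.shape}")
    if well_id is None or field_index is None:
        m = re.match(r"^([A-H]\d{2})_f(\d+)$", path.stem)
        if not m:
            raise FormatError(
                f"{path}: cannot infer well/field from file name; "
                "expected <well>_f<field>.tif")
        well_id = well_id or m.group(1)
        field_index = field_index if field_index is not None else int(m.group(2))
    with tifffile.TiffFile(path) as tf:
        meta = tf.shaped_metadata or tf.imagej_metadata
    if isinstance(meta, (list, tuple)) and meta:
        meta = meta[0]
    if isinstance(meta, dict) and "pixel_size_um" in meta:
        pixel_size_um = float(meta["pixel_size_um"])
    return FieldImage(well_id=well_id, field_index=field_index,
                      nuclei_ch=data[0], mito_ch=data[1], mros_ch=data[2],
                      pixel_size_um=pixel_size_um)


def load_plate_images(directory: Union[str, Path],
                      layout: PlateLayout) -> Dict[str, List[FieldImage]]:
    """Load all ``<well>_f<k>.tif`` fields for the layout's imaged wells."""
    directory = Path(directory)
    fields: Dict[str, List[FieldImage]] = {}
    for spec in layout.wells:
        if spec.role == "empty":
            continue
        paths = sorted(directory.glob(f"{spec.well_id}_f*.tif"))
        if paths:
            fields[spec.well_id] = [
                read_field(p, pixel_size_um=layout.pixel_size_um)
                for p in paths]
    return fields


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineParams:
    """Analysis parameters for one quantification run.

    ``bg_method`` selects the background correction applied to the superoxide
    channel before masked measurement ('parabola', 'well' or 'none'); the
    mitochondrial channel used for the membrane-potential RFU is left
    uncorrected by default (``correct_mito_channel``).
    """

    bg_method: str = "parabola"
    parabola_curvature: float = DEFAULT_CURVATURE
    correct_mito_channel: bool = False
    control_condition: Optional[str] = None  # default: negative-control wells
    min_nucleus_area_px: int = 30
    smoothing_sigma: float = 2.0
    exclude_border_nuclei: bool = True
    mito_min_object_px: int = 4
    seed: Optional[int] = None  # recorded for provenance

    def __post_init__(self) -> None:
        if self.bg_method not in ("parabola", "well", "none"):
            raise ValueError("bg_method must be 'parabola', 'well' or 'none'")


@dataclass
class PipelineResult:
    """Tables and statistics produced by :func:`run_pipeline`."""

    cells: pd.DataFrame        # one row per retained cell
    wells: pd.DataFrame        # one row per analysed well (incl. flagged)
    conditions: pd.DataFrame   # one row per condition
    stats: dict                # per-comparison statistics vs control
    background_value: Optional[float] = None


def _resolve_background(layout: PlateLayout,
                        fields: Mapping[str, Sequence[FieldImage]],
                        params: PipelineParams) -> BackgroundModel:
    if params.bg_method == "parabola":
        return BackgroundModel("sliding_parabola",
                               curvature=params.parabola_curvature)
    if params.bg_method == "none":
        return BackgroundModel("none", curvature=None)
    bg_wells = layout.background_wells
    if not bg_wells:
        raise LayoutError("bg_method 'well' requires >= 1 background_well "
                          "in the layout")
    means = [float(f.mros_ch.mean())
             for w in bg_wells for f in fields.get(w, [])]
    if not means:
        raise LayoutError("bg_method 'well': no images found for the "
                          "background wells")
    return BackgroundModel("background_well", curvature=None,
                           background_value=float(np.mean(means)))


def run_pipeline(layout: PlateLayout,
                 fields: Union[str, Path, Mapping[str, Sequence[FieldImage]]],
                 params: PipelineParams = PipelineParams(),
                 out_dir: Optional[Union[str, Path]] = None) -> PipelineResult:
    """Run the full quantification workflow over a plate.

    Per field: background-correct the superoxide channel, segment nuclei,
    assign a cell region per nucleus, extract its mitochondrial mask, and
    measure the masked superoxide signal, mean mitochondrial-channel RFU
    (membrane-potential proxy) and mitochondrial area per cell.  Per-cell
    records are averaged within wells, wells within conditions, and condition
    means expressed as percent of the control condition.  Two-group tests of
    each condition against the control (on replicate-well means) are written
    to the statistics report.

    ``fields`` is either a directory of ``<well>_f<k>.tif`` files or an
    in-memory mapping well_id -> list of :class:`FieldImage`.  Wells in which
    no cell is detected in any field are flagged ``no-cells`` and excluded
    from condition means.  The run is deterministic given identical inputs.

    When ``out_dir`` is given, writes ``cells.csv``, ``wells.csv``,
    ``conditions.csv``, ``stats.json`` and ``run.log`` (software version and
    all parameters).
    """
    from . import __version__
    from .quantify import aggregate_condition, measure_cells, summarize_well
    from .segment import segment_field
    from .screenstats import t_test

    if not isinstance(fields, Mapping):
        fields = load_plate_images(fields, layout)

    bg_model = _resolve_background(layout, fields, params)

    cell_rows: List[dict] = []
    well_rows: List[dict] = []
    measured_wells = [w for w in layout.wells
                      if w.role not in ("background_well", "empty")
                      and w.well_id in fields]
    for spec in measured_wells:
        well_cells = []
        for f in fields[spec.well_id]:
            seg = segment_field(
                f,
                min_nucleus_area_px=params.min_nucleus_area_px,
                smoothing_sigma=params.smoothing_sigma,
                exclude_border=params.exclude_border_nuclei,
                mito_min_object_px=params.mito_min_object_px)
            well_cells.extend(measure_cells(
                f, seg, bg_model,
                correct_mito_channel=params.correct_mito_channel))
        for c in well_cells:
            cell_rows.append(dataclasses.asdict(c))
        if not well_cells:
            logger.warning("well %s: no cells detected in any field; "
                           "flagged and excluded from condition mean",
                           spec.well_id)
            well_rows.append({
                "well_id": spec.well_id, "condition": spec.condition,
                "role": spec.role, "dose_nM": spec.dose_nM,
                "n_cells": 0, "mean_mros_per_cell": np.nan,
                "mean_mito_rfu": np.nan, "mean_mito_area_um2": np.nan,
                "flag": "no-cells"})
        else:
            ws = summarize_well(well_cells)
            well_rows.append({
                "well_id": spec.well_id, "condition": spec.condition,
                "role": spec.role, "dose_nM": spec.dose_nM,
                "n_cells": ws.n_cells,
                "mean_mros_per_cell": ws.mean_mros_per_cell,
                "mean_mito_rfu": ws.mean_mito_rfu,
                "mean_mito_area_um2": ws.mean_mito_area_um2,
                "flag": ""})

    cells_df = pd.DataFrame(cell_rows)
    wells_df = pd.DataFrame(well_rows)

    if params.control_condition is not None:
        control = params.control_condition
    else:
        neg = [w for w in measured_wells if w.role == "negative_control"]
        control = neg[0].condition if neg else (
            measured_wells[0].condition if measured_wells else None)

    valid = wells_df[wells_df["flag"] == ""] if len(wells_df) else wells_df
    conditions_df = aggregate_condition(valid, control_condition=control)

    stats: dict = {"control_condition": control, "comparisons": []}
    if control is not None and len(valid):
        ctrl_vals = valid.loc[valid["condition"] == control,
                              "mean_mros_per_cell"].to_numpy()
        for cond, grp in valid.groupby("condition", sort=True):
            if cond == control:
                continue
            vals = grp["mean_mros_per_cell"].to_numpy()
            if len(vals) >= 2 and len(ctrl_vals) >= 2:
                res = t_test(vals, ctrl_vals)
                stats["comparisons"].append({
                    "condition": cond, "vs": control,
                    "test": res.test, "statistic": res.statistic,
                    "df": res.df, "p": res.p,
                    "mean_difference": res.mean_difference,
                    "ci95": [res.ci95_low, res.ci95_high],
                    "n": list(res.n)})

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cells_df.to_csv(out_dir / "cells.csv", index=False)
        wells_df.to_csv(out_dir / "wells.csv", index=False)
        conditions_df.to_csv(out_dir / "conditions.csv", index=False)
        with open(out_dir / "stats.json", "w") as fh:
            json.dump(stats, fh, indent=2)
        with open(out_dir / "run.log", "w") as fh:
            fh.write(f"mitoscreen {__version__}\n")
            fh.write(f"background: {bg_model}\n")
            fh.write(f"params: {params}\n")
            fh.write(f"seed: {params.seed}\n")
            fh.write(f"wells analysed: {len(well_rows)}; "
                     f"cells: {len(cell_rows)}\n")

    return PipelineResult(cells=cells_df, wells=wells_df,
                          conditions=conditions_df, stats=stats,
                          background_value=bg_model.background_value)
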