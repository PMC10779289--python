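"""Synthetic 3-channel plate generator with known ground truth.

Emulates fields of adherent endothelial cells imaged in three channels:
nuclei (compact bright blobs), a perinuclear mitochondrial network (granular
texture of small anisotropic kernels scattered in an annulus around each
nucleus), and a superoxide-reporter channel whose mitochondria-colocalized
component is a condition-level multiple ``s`` of the mitochondrial texture.
A tunable fraction of the reporter signal is placed outside mitochondria (a
cytoplasmic, non-specific component), a smooth parabolic illumination surface
is added, and Poisson shot noise plus Gaussian read noise complete the
camera model.  Every stochastic element derives from a seed, and the exact
per-pixel ground truth (masks, texture sums, condition scale) is returned
alongside each field, so downstream segmentation and quantification can be
validated against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .model_io import (DEFAULT_PIXEL_SIZE_UM, FieldImage, PlateLayout,
                       save_layout, write_field)

__all__ = [
    "SimulationParams", "ConditionEffect", "SyntheticGroundTruth",
    "PlateSimulation", "GenerationError",
    "simulate_field", "simulate_plate", "four_pl", "write_plate",
]


class GenerationError(RuntimeError):
    """Raised when a field cannot be generated under the requested geometry."""


def four_pl(dose: np.ndarray, top: float, bottom: float,
            ic50: float, hill: float) -> np.ndarray:
    """Four-parameter logistic: ``bottom + (top-bottom)/(1+(dose/ic50)^hill)``."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


# ---------------------------------------------------------------------------
# parameters and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationParams:
    """Geometry, photometry and noise of one simulated field.

    Defaults emulate a 256x256 px field (~154 um at 0.6 um/px) of adherent
    endothelial cells: nuclei of radius ~6 px, mitochondrial granules of
    ~1-2 px width and a few hundred RFU amplitude, a parabolic illumination
    bowl of 150 RFU amplitude over the field, Poisson shot noise and 3 RFU
    Gaussian read noise.
    """

    shape: Tuple[int, int] = (256, 256)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    # nuclei
    nucleus_radius_px: float = 6.0
    nucleus_radius_sd_px: float = 0.8
    min_separation_px: float = 20.0
    border_margin_px: float = 14.0
    nucleus_amplitude: float = 800.0
    nucleus_offset: float = 20.0
    # mitochondria
    kernels_per_cell: int = 28
    kernel_amplitude: float = 250.0
    kernel_amplitude_sd_log: float = 0.3
    kernel_sigma_long_px: float = 2.2
    kernel_sigma_short_px: float = 0.9
    annulus_inner: float = 1.3   # multiples of nucleus radius
    annulus_outer: float = 2.8
    mask_cutoff: float = 40.0    # texture level defining the true mito mask
    mito_offset: float = 20.0
    cytoplasm_radius_factor: float = 3.4
    # superoxide-channel background surface (2-D quadratic bowl)
    background_base: float = 50.0
    background_amplitude: float = 150.0
    background_center: Optional[Tuple[float, float]] = None  # default: centre
    # noise
    poisson_noise: bool = True
    gaussian_noise_sd: float = 3.0


@dataclass(frozen=True)
class ConditionEffect:
    """Condition-level multipliers applied by :func:`simulate_plate`.

    ``s`` scales the mitochondria-colocalized superoxide signal.
    ``nonspecific_fraction`` (if set) overrides the simulation default for
    the fraction of total reporter signal placed outside mitochondria;
    stimuli that also raise cytosolic probe oxidation are modelled by giving
    the stimulated condition a larger fraction.  ``viability`` scales the
    expected number of cells per field.
    """

    s: float = 1.0
    nonspecific_fraction: Optional[float] = None
    viability: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.s) and self.s >= 0):
            raise ValueError("s must be finite and >= 0")
        if self.nonspecific_fraction is not None and not (
                0 <= self.nonspecific_fraction < 1):
            raise ValueError("nonspecific_fraction must be in [0, 1)")
        if not 0 <= self.viability <= 1:
            raise ValueError("viability must be in [0, 1]")


@dataclass
class SyntheticGroundTruth:
    """Exact per-field truth accompanying a simulated :class:`FieldImage`."""

    centers: np.ndarray            # (n_cells, 2) float, (row, col)
    radii: np.ndarray              # (n_cells,) nucleus radii, px
    mito_truth_labels: np.ndarray  # int label map; cell k+1 owns its pixels
    masked_texture_sums: np.ndarray  # per cell: sum of texture on its mask
    s: float                       # superoxide scale factor of the condition
    nonspecific_fraction: float
    background_coeffs: Tuple[float, float, float, float]  # base, amp, cy, cx
    gaussian_noise_sd: float
    poisson_noise: bool

    @property
    def n_cells(self) -> int:
        return len(self.radii)

    def background_surface(self, shape: Tuple[int, int]) -> np.ndarray:
        base, amp, cy, cx = self.background_coeffs
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        norm = (max(shape) / 2.0) ** 2
        return base + amp * r2 / norm


# ---------------------------------------------------------------------------
# field simulation
# ---------------------------------------------------------------------------

def _place_centers(n: int, shape, margin: float, min_sep: float,
                   rng: np.random.Generator, max_tries: int = 400) -> np.ndarray:
    centers: List[Tuple[float, float]] = []
    lo_r, hi_r = margin, shape[0] - margin
    lo_c, hi_c = margin, shape[1] - margin
    if n > 0 and (hi_r <= lo_r or hi_c <= lo_c):
        raise GenerationError("field too small for the requested margin")
    for _ in range(n):
        for _attempt in range(max_tries):
            cand = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
            if all((cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= min_sep ** 2
                   for r, c in centers):
                centers.append(cand)
                break
        else:
            raise GenerationError(
                f"could not place {n} cells at separation {min_sep} px "
                f"in a {shape} field; request fewer cells")
    return np.asarray(centers, dtype=float).reshape(n, 2)


def _stamp(canvas: np.ndarray, cy: float, cx: float, patch_radius: int,
           values_fn) -> None:
    """Add ``values_fn(dy, dx)`` to ``canvas`` on a clipped bounding box."""
    h, w = canvas.shape
    r0 = max(0, int(cy) - patch_radius)
    r1 = min(h, int(cy) + patch_radius + 1)
    c0 = max(0, int(cx) - patch_radius)
    c1 = min(w, int(cx) + patch_radius + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1].astype(float)
    canvas[r0:r1, c0:c1] += values_fn(yy - cy, xx - cx)


def simulate_field(
    n_cells: int,
    params: SimulationParams = SimulationParams(),
    s: float = 1.0,
    nonspecific_fraction: float = 0.0,
    seed: Union[int, np.random.Generator, None] = 0,
    well_id: str = "A01",
    field_index: int = 0,
) -> Tuple[FieldImage, SyntheticGroundTruth]:
    """Simulate one 3-channel field with ground truth.

    The mitochondria-colocalized superoxide signal is exactly
    ``s * texture`` on the true mitochondrial mask (texture above
    ``params.mask_cutoff``); with ``nonspecific_fraction`` f > 0, an
    additional cytoplasmic component totalling ``f / (1 - f)`` times each
    cell's masked signal is spread uniformly over a perinuclear disc
    excluding the mask, so f is the fraction of total cellular reporter
    signal lying outside mitochondria.  Channels are rendered before noise in
    a fixed order, so the nuclei and mitochondria channels are identical
    across conditions differing only in ``s`` or f (given the same seed).
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if params.shape[0] < 64 or params.shape[1] < 64:
        raise ValueError("field must be at least 64x64 px")
    if not 0 <= nonspecific_fraction < 1:
        raise ValueError("nonspecific_fraction must be in [0, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    shape = params.shape

    centers = _place_centers(n_cells, shape, params.border_margin_px,
                             params.min_separation_px, rng)
    radii = np.clip(rng.normal(params.nucleus_radius_px,
                               params.nucleus_radius_sd_px, n_cells),
                    2.0, None)

    nuclei = np.zeros(shape)
    texture = np.zeros(shape)
    owner_tex = np.zeros(shape)          # strongest single-cell texture
    owner = np.zeros(shape, dtype=np.int32)

    for k in range(n_cells):
        cy, cx = centers[k]
        r = radii[k]
        amp = params.nucleus_amplitude * rng.uniform(0.9, 1.1)
        _stamp(nuclei, cy, cx, int(np.ceil(2.2 * r)),
               lambda dy, dx, r=r, amp=amp:
               amp * np.exp(-((dy ** 2 + dx ** 2) / r ** 2) ** 2))

        cell_tex = np.zeros(shape)
        n_k = params.kernels_per_cell
        rho = rng.uniform(params.annulus_inner * r,
                          params.annulus_outer * r, n_k)
        phi = rng.uniform(0, 2 * np.pi, n_k)
        amps = params.kernel_amplitude * rng.lognormal(
            0.0, params.kernel_amplitude_sd_log, n_k)
        thetas = rng.uniform(0, np.pi, n_k)
        for kcy, kcx, a, th in zip(cy + rho * np.sin(phi),
                                   cx + rho * np.cos(phi), amps, thetas):
            ct, st = np.cos(th), np.sin(th)
            sl, ss = params.kernel_sigma_long_px, params.kernel_sigma_short_px
            _stamp(cell_tex, kcy, kcx, int(np.ceil(3.5 * sl)),
                   lambda dy, dx, a=a, ct=ct, st=st, sl=sl, ss=ss:
                   a * np.exp(-((dx * ct + dy * st) ** 2 / (2 * sl ** 2)
                                + (-dx * st + dy * ct) ** 2 / (2 * ss ** 2))))
        texture += cell_tex
        stronger = cell_tex > owner_tex
        owner_tex[stronger] = cell_tex[stronger]
        owner[stronger] = k + 1

    mask = texture > params.mask_cutoff
    truth_labels = np.where(mask, owner, 0).astype(np.int32)
    masked_texture = np.where(mask, texture, 0.0)
    sums = np.bincount(truth_labels.ravel(),
                       weights=masked_texture.ravel(),
                       minlength=n_cells + 1)[1:]

    mros = s * masked_texture
    if nonspecific_fraction > 0 and n_cells > 0:
        ns_canvas = np.zeros(shape)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        for k in range(n_cells):
            cy, cx = centers[k]
            disc = ((yy - cy) ** 2 + (xx - cx) ** 2
                    <= (params.cytoplasm_radius_factor * radii[k]) ** 2)
            disc &= ~mask
            n_px = int(disc.sum())
            if n_px == 0:
                continue
            total = (nonspecific_fraction / (1 - nonspecific_fraction)
                     * s * sums[k])
            ns_canvas[disc] += total / n_px
        mros = mros + ns_canvas

    cy0, cx0 = (params.background_center
                if params.background_center is not None
                else ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0))
    coeffs = (params.background_base, params.background_amplitude, cy0, cx0)
    truth = SyntheticGroundTruth(
        centers=centers, radii=radii, mito_truth_labels=truth_labels,
        masked_texture_sums=sums, s=s,
        nonspecific_fraction=nonspecific_fraction,
        background_coeffs=coeffs,
        gaussian_noise_sd=params.gaussian_noise_sd,
        poisson_noise=params.poisson_noise)

    mros = mros + truth.background_surface(shape)
    nuclei = nuclei + params.nucleus_offset
    mito = texture + params.mito_offset

    channels = []
    for ch in (nuclei, mito, mros):  # fixed order keeps streams aligned
        out = ch
        if params.poisson_noise:
            out = rng.poisson(out).astype(float)
        if params.gaussian_noise_sd > 0:
            out = out + rng.normal(0.0, params.gaussian_noise_sd, shape)
        channels.append(np.clip(out, 0.0, None))

    field_img = FieldImage(well_id=well_id, field_index=field_index,
                           nuclei_ch=channels[0], mito_ch=channels[1],
                           mros_ch=channels[2],
                           pixel_size_um=params.pixel_size_um)
    return field_img, truth


# ---------------------------------------------------------------------------
# plate simulation
# ---------------------------------------------------------------------------

@dataclass
class PlateSimulation:
    """Fields, per-field truth, and a tidy truth table for one plate."""

    layout: PlateLayout
    fields: Dict[str, List[FieldImage]]
    truth: Dict[Tuple[str, int], SyntheticGroundTruth]
    truth_table: pd.DataFrame
    seed: int


def simulate_plate(
    layout: PlateLayout,
    effects: Mapping[str, ConditionEffect],
    seed: int = 0,
    n_cells_per_field: int = 30,
    params: SimulationParams = SimulationParams(),
) -> PlateSimulation:
    """Simulate every imaged well of a plate under a condition effect spec.

    ``effects`` maps each cell-bearing condition of ``layout`` to its
    :class:`ConditionEffect`; replicate wells of one condition share the
    condition parameters but receive independent per-well seeds (derived
    deterministically from the master seed), so their realized noise and
    cell placements differ.  Background wells are rendered with zero cells
    (illumination surface and noise only); ``empty`` wells are not imaged.
    Cell counts per field are Poisson around
    ``n_cells_per_field * viability``.
    """
    groups = layout.replicate_groups
    for cond in effects:
        if cond not in groups:
            raise ValueError(f"effect condition {cond!r} not present in "
                             "the layout")
    missing = [c for c in groups if c not in effects]
    if missing:
        raise ValueError(f"layout conditions without an effect spec: "
                         f"{missing}")

    imaged = sorted(w.well_id for w in layout.wells if w.role != "empty")
    children = np.random.SeedSequence(seed).spawn(len(imaged))
    well_rngs = {w: np.random.default_rng(ss)
                 for w, ss in zip(imaged, children)}

    fields: Dict[str, List[FieldImage]] = {}
    truth: Dict[Tuple[str, int], SyntheticGroundTruth] = {}
    rows: List[dict] = []
    for spec in layout.wells:
        if spec.role == "empty":
            continue
        rng = well_rngs[spec.well_id]
        if spec.role == "background_well":
            eff = ConditionEffect(s=0.0, viability=0.0)
        else:
            eff = effects[spec.condition]
        f_ns = (eff.nonspecific_fraction
                if eff.nonspecific_fraction is not None else 0.0)
        expected = n_cells_per_field * eff.viability
        well_fields: List[FieldImage] = []
        for fi in range(layout.fields_per_well):
            n = int(rng.poisson(expected)) if expected > 0 else 0
            img, tr = simulate_field(
                n, params=params, s=eff.s, nonspecific_fraction=f_ns,
                seed=rng, well_id=spec.well_id, field_index=fi)
            well_fields.append(img)
            truth[(spec.well_id, fi)] = tr
            rows.append({
                "well_id": spec.well_id, "field_index": fi,
                "condition": spec.condition, "role": spec.role,
                "dose_nM": spec.dose_nM, "s": eff.s,
                "nonspecific_fraction": f_ns, "n_cells_true": tr.n_cells,
                "masked_texture_total": float(tr.masked_texture_sums.sum()),
            })
        fields[spec.well_id] = well_fields
    return PlateSimulation(layout=layout, fields=fields, truth=truth,
                           truth_table=pd.DataFrame(rows), seed=seed)


def write_plate(sim: PlateSimulation, out_dir: Union[str, Path]) -> Path:
    """Write a simulated plate to disk: TIFF fields, truth.csv, layout.yaml."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for well_fields in sim.fields.values():
        for f in well_fields:
            write_field(f, out_dir)
    sim.truth_table.to_csv(out_dir / "truth.csv", index=False)
    save_layout(sim.layout, out_dir / "layout.yaml")
    return out_dir
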