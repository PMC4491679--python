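"""Dose grids, structure masks, DVHs, and per-organ plan summaries.

A plan is represented as a 3-D dose raster (:class:`DoseGrid`) plus aligned
boolean organ masks (:class:`StructureMask`).  The module provides the
standard plan-evaluation operations: normalising a plan so the mean clinical
target volume (CTV) dose equals the prescription, combining fields with a
per-field CTV prescription, cumulative dose-volume histograms, and per-organ
max/mean summary tables with plan-to-plan comparison.

Conventions: grids live in a right-handed patient coordinate system
(x: left-right, y: anterior-posterior, z: inferior-superior), arrays are
indexed ``values[ix, iy, iz]`` with 0-based indices and a voxel-centre
origin.  A voxel belongs to a structure iff its centre is inside — there is
no partial-volume weighting, and summary statistics depend on that choice.

Grids and masks round-trip through NRRD files (one scalar volume per file,
masks as 0/1) via SimpleITK.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseGrid",
    "StructureMask",
    "DVHCurve",
    "OrganDoseStats",
    "PlanSummary",
    "normalize_to_ctv_mean",
    "combine_fields",
    "cumulative_dvh",
    "dose_summary",
    "compare_summaries",
    "read_dose_grid",
    "write_dose_grid",
    "read_structure_mask",
    "write_structure_mask",
    "load_reference_plan_summaries",
]

DEFAULT_PRESCRIPTION_GY = 76.0
DEFAULT_PER_FIELD_PRESCRIPTION_GY = 34.5
DEFAULT_DVH_BIN_GY = 0.1


class DosimetryError(ValueError):
    """Raised for invalid grids, masks, or mismatched geometries."""


def _validate_geometry(values, spacing, origin) -> tuple[tuple, tuple]:
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if values.ndim != 3:
        raise DosimetryError(f"expected a 3-D array, got shape {values.shape}")
    if len(spacing) != 3 or len(origin) != 3:
        raise DosimetryError("spacing and origin must have three components")
    if any(s <= 0 for s in spacing):
        raise DosimetryError(f"spacing must be strictly positive, got {spacing}")
    return spacing, origin


@dataclass(frozen=True)
class DoseGrid:
    """3-D dose raster in Gy (RBE), indexed ``values[ix, iy, iz]``."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        spacing, origin = _validate_geometry(values, self.spacing, self.origin)
        if np.any(values < 0):
            raise DosimetryError("dose values must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def scaled(self, factor: float) -> "DoseGrid":
        return DoseGrid(self.values * factor, self.spacing, self.origin)


@dataclass(frozen=True)
class StructureMask:
    """Boolean organ mask aligned voxel-for-voxel with its dose grid."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = "structure"

    def __post_init__(self) -> None:
        values = np.asarray(self.values).astype(bool)
        spacing, origin = _validate_geometry(values, self.spacing, self.origin)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing))

    def same_geometry(self, other) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def _masked_doses(grid: DoseGrid, mask: StructureMask) -> np.ndarray:
    if not grid.same_geometry(mask):
        raise DosimetryError(
            f"mask {mask.label!r} geometry does not match the dose grid "
            f"({mask.values.shape} vs {grid.values.shape})"
        )
    if mask.voxel_count == 0:
        raise DosimetryError(f"structure {mask.label!r} is empty")
    return grid.values[mask.values]


def normalize_to_ctv_mean(
    grid: DoseGrid, ctv: StructureMask, prescription: float = DEFAULT_PRESCRIPTION_GY
) -> DoseGrid:
    """Uniformly rescale a plan so the mean CTV dose equals the prescription.

    Idempotent, and scale-equivariant: any positive prefactor on the input
    grid is absorbed by the normalisation.
    """
    if prescription <= 0:
        raise DosimetryError(f"prescription must be positive, got {prescription}")
    current = float(_masked_doses(grid, ctv).mean())
    if current <= 0:
        raise DosimetryError("mean CTV dose is zero; cannot normalize")
    return grid.scaled(prescription / current)


def combine_fields(
    fields: Sequence[DoseGrid],
    ctv: StructureMask,
    per_field_prescription: float = DEFAULT_PER_FIELD_PRESCRIPTION_GY,
) -> DoseGrid:
    """Scale each field to the per-field mean CTV dose, then sum.

    With the default 34.5 Gy per field, a two-field lateral-opposed plan
    delivers a mean CTV dose of 69 Gy.  Field order does not matter.
    """
    if not fields:
        raise DosimetryError("at least one field is required")
    first = fields[0]
    for f in fields[1:]:
        if not first.same_geometry(f):
            raise DosimetryError("all fields must share grid shape, spacing, and origin")
    total = np.zeros_like(first.values)
    for f in fields:
        total += normalize_to_ctv_mean(f, ctv, per_field_prescription).values
    return DoseGrid(total, first.spacing, first.origin)


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram.

    ``volume_fraction[i]`` is the percentage of the structure volume
    receiving at least ``dose_edges[i]`` Gy; it starts at 100% at zero dose
    and reaches 0% above the maximum dose.
    """

    dose_edges: np.ndarray
    volume_fraction: np.ndarray
    label: str = "structure"

    def __post_init__(self) -> None:
        edges = np.asarray(self.dose_edges, dtype=float)
        frac = np.asarray(self.volume_fraction, dtype=float)
        if edges.shape != frac.shape:
            raise DosimetryError("dose_edges and volume_fraction must have equal length")
        if np.any(np.diff(edges) <= 0):
            raise DosimetryError("dose_edges must be strictly ascending")
        object.__setattr__(self, "dose_edges", edges)
        object.__setattr__(self, "volume_fraction", frac)

    def volume_at_dose(self, dose: float) -> float:
        """V(dose): % of the structure receiving at least ``dose`` Gy.

        Exact bin edges return their tabulated value; doses between edges
        return the next edge's value (the conservative lower bound).
        """
        idx = int(np.searchsorted(self.dose_edges, dose, side="left"))
        if idx >= len(self.volume_fraction):
            return 0.0
        return float(self.volume_fraction[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_Gy": self.dose_edges, "volume_pct": self.volume_fraction}
        )


def cumulative_dvh(
    grid: DoseGrid, mask: StructureMask, bin_width: float = DEFAULT_DVH_BIN_GY
) -> DVHCurve:
    """Cumulative DVH evaluated at bin edges 0, w, 2w, ... above the max dose."""
    if bin_width <= 0:
        raise DosimetryError(f"bin_width must be positive, got {bin_width}")
    doses = _masked_doses(grid, mask)
    n_edges = int(np.floor(doses.max() / bin_width)) + 2
    edges = np.arange(n_edges) * bin_width
    fraction = 100.0 * (doses[None, :] >= edges[:, None]).mean(axis=1)
    return DVHCurve(dose_edges=edges, volume_fraction=fraction, label=mask.label)


class OrganDoseStats(NamedTuple):
    max: float
    mean: float


@dataclass(frozen=True)
class PlanSummary:
    """Per-organ max/mean dose table for one plan.

    Structures that could not be summarised (e.g. empty masks) are listed in
    ``errors`` rather than silently dropped.
    """

    label: str
    organs: dict[str, OrganDoseStats]
    errors: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"organ": organ, "max_Gy": s.max, "mean_Gy": s.mean}
                for organ, s in self.organs.items()
            ]
        )


def dose_summary(
    grid: DoseGrid, masks: Iterable[StructureMask], label: str = "plan"
) -> PlanSummary:
    """Per-organ max and mean dose over masked voxels."""
    organs: dict[str, OrganDoseStats] = {}
    errors: dict[str, str] = {}
    empty = True
    for mask in masks:
        empty = False
        try:
            doses = _masked_doses(grid, mask)
        except DosimetryError as exc:
            errors[mask.label] = str(exc)
            continue
        organs[mask.label] = OrganDoseStats(max=float(doses.max()), mean=float(doses.mean()))
    if empty:
        raise DosimetryError("at least one structure mask is required")
    return PlanSummary(label=label, organs=organs, errors=errors)


def compare_summaries(a: PlanSummary, b: PlanSummary) -> dict[str, OrganDoseStats]:
    """Signed per-organ deltas (b - a) for max and mean dose."""
    if set(a.organs) != set(b.organs):
        raise DosimetryError(
            f"organ sets differ: only in {a.label!r}: {sorted(set(a.organs) - set(b.organs))}, "
            f"only in {b.label!r}: {sorted(set(b.organs) - set(a.organs))}"
        )
    return {
        organ: OrganDoseStats(
            max=b.organs[organ].max - a.organs[organ].max,
            mean=b.organs[organ].mean - a.organs[organ].mean,
        )
        for organ in a.organs
    }


# --- NRRD I/O ---------------------------------------------------------------
# SimpleITK images index as (x, y, z) but expose arrays as (z, y, x); the
# transposes below keep the package's values[ix, iy, iz] convention.


def _write_volume(values: np.ndarray, spacing, origin, path) -> None:
    import SimpleITK as sitk

    image = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    image.SetSpacing(tuple(float(s) for s in spacing))
    image.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(image, str(path))


def _read_volume(path) -> tuple[np.ndarray, tuple, tuple]:
    import SimpleITK as sitk

    image = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(image).transpose(2, 1, 0)
    return values, tuple(image.GetSpacing()), tuple(image.GetOrigin())


def write_dose_grid(grid: DoseGrid, path) -> None:
    """Write a dose grid as a scalar NRRD volume."""
    _write_volume(grid.values, grid.spacing, grid.origin, path)


def read_dose_grid(path) -> DoseGrid:
    """Read a scalar NRRD volume as a dose grid."""
    values, spacing, origin = _read_volume(path)
    return DoseGrid(values=values, spacing=spacing, origin=origin)


def write_structure_mask(mask: StructureMask, path) -> None:
    """Write a structure mask as a 0/1 NRRD volume."""
    _write_volume(mask.values.astype(np.uint8), mask.spacing, mask.origin, path)


def read_structure_mask(path, label: str = "structure") -> StructureMask:
    """Read a 0/1 NRRD volume as a structure mask."""
    values, spacing, origin = _read_volume(path)
    return StructureMask(values=values > 0, spacing=spacing, origin=origin, label=label)


def load_reference_plan_summaries(path=None) -> dict[str, PlanSummary]:
    """Published per-organ dose summaries for the three planning techniques.

    Returns summaries keyed ``SOC`` (custom aperture + range compensator),
    ``MLC+RC`` (multileaf collimator + range compensator) and ``MLC-only``,
    averaged over a ten-patient cohort and normalised to a 76 Gy (RBE) mean
    CTV dose.  Values are transcribed as printed; note the anterior-rectal-
    wall mean under both MLC techniques (75.90 Gy) duplicates the CTV row
    and is inconsistent with the SOC mean of 39.48 Gy — the printed values
    are preserved without correction.
    """
    if path is None:
        with resources.files("protonplan.data").joinpath("cohort_plan_summaries.csv").open() as fh:
            frame = pd.read_csv(fh)
    else:
        frame = pd.read_csv(path)
    plans = {"SOC": ("soc_max", "soc_mean"), "MLC+RC": ("mlc_rc_max", "mlc_rc_mean"),
             "MLC-only": ("mlc_only_max", "mlc_only_mean")}
    out = {}
    for label, (max_col, mean_col) in plans.items():
        organs = {
            str(rec["organ"]): OrganDoseStats(max=float(rec[max_col]), mean=float(rec[mean_col]))
            for rec in frame.to_dict("records")
        }
        out[label] = PlanSummary(label=label, organs=organs)
    return out
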