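"""Seeded generators for synthetic plans, neutron tables, and apertures.

Every generator is a pure function of its spec (including the seed):
repeated calls return bit-identical results.  The generators emulate the
*structure* of passively scattered proton prostate plans — not the physics:

* :func:`gen_plan` builds a lateral opposed-pair of dose fields on a 3-D
  grid with ellipsoidal pelvic structures.  Each field's depth profile is a
  flat spread-out-Bragg-peak (SOBP) plateau ending at the beam range with a
  sigmoid distal falloff and a lower entrance plateau; the lateral profile
  is a product of error-function penumbrae.  Ranges are drawn from
  22.0-27.1 cm water-equivalent, SOBP widths from 8-10 cm, and clinical
  target volume (CTV) ellipsoids are constrained to 46.3-81.8 cm^3.
* :func:`gen_neutron_table` produces paired per-organ neutron
  equivalent-dose tables for a standard-of-care (SOC) plan and an MLC-only
  plan, anchored to published Monte Carlo values, preserving the structural
  signature that replacing the custom aperture with an MLC lowers the
  external (treatment-head) component and raises the internal (in-patient)
  component for every organ.
* :func:`gen_aperture` draws a simple closed aperture outline as a radial
  Fourier perturbation of a circle.

None of this stands in for particle transport; see the package docs for
what the stylisation does and does not cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.special import erf

from .dosimetry import DoseGrid, StructureMask
from .mlc import AperturePolygon
from .risk import OrganNeutronDose, neutron_doses_mlc_only, neutron_doses_soc

__all__ = [
    "SyntheticPlanSpec",
    "SyntheticNeutronSpec",
    "SyntheticPlan",
    "CTV_VOLUME_BOUNDS_CM3",
    "BEAM_RANGE_BOUNDS_CM",
    "SOBP_WIDTH_BOUNDS_CM",
    "PLAN_VARIANTS",
    "gen_plan",
    "gen_neutron_table",
    "gen_aperture",
]

CTV_VOLUME_BOUNDS_CM3 = (46.3, 81.8)
BEAM_RANGE_BOUNDS_CM = (22.0, 27.1)
SOBP_WIDTH_BOUNDS_CM = (8.0, 10.0)

#: Stylised penumbra widening per planning technique: the MLC-only field
#: edge is slightly broadened by scalloping and the larger air gap.
PLAN_VARIANTS = {"SOC": 1.0, "MLC+RC": 1.0, "MLC-only": 1.06}


class SyntheticDataError(ValueError):
    """Raised when a spec is invalid or a generator exhausts its retries."""


@dataclass(frozen=True)
class SyntheticPlanSpec:
    """Parameters of a synthetic opposed-lateral proton plan.

    ``ctv_semi_axes``, ``beam_range`` and ``sobp_width`` may be left unset to
    be drawn (seeded) from their clinical intervals; explicit values are
    validated against the same bounds.
    """

    seed: int = 0
    shape: tuple[int, int, int] = (64, 40, 40)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    ctv_semi_axes: tuple[float, float, float] | None = None
    beam_range: float | None = None
    sobp_width: float | None = None
    penumbra_sigma: float = 0.35
    noise_amplitude: float = 0.01
    variant: str = "SOC"

    def __post_init__(self) -> None:
        if self.variant not in PLAN_VARIANTS:
            raise SyntheticDataError(
                f"unknown variant {self.variant!r}; expected one of {sorted(PLAN_VARIANTS)}"
            )
        if any(n < 1 for n in self.shape) or any(s <= 0 for s in self.spacing):
            raise SyntheticDataError("shape must be >= 1 and spacing positive in every axis")
        if self.penumbra_sigma <= 0:
            raise SyntheticDataError("penumbra_sigma must be positive")
        if self.noise_amplitude < 0:
            raise SyntheticDataError("noise_amplitude must be non-negative")
        if self.ctv_semi_axes is not None:
            vol = _ellipsoid_volume(self.ctv_semi_axes)
            lo, hi = CTV_VOLUME_BOUNDS_CM3
            if not lo <= vol <= hi:
                raise SyntheticDataError(
                    f"CTV volume {vol:.1f} cm^3 outside the clinical interval [{lo}, {hi}]"
                )
        if self.beam_range is not None and not (
            BEAM_RANGE_BOUNDS_CM[0] <= self.beam_range <= BEAM_RANGE_BOUNDS_CM[1]
        ):
            raise SyntheticDataError(
                f"beam_range {self.beam_range} cm outside {BEAM_RANGE_BOUNDS_CM}"
            )
        if self.sobp_width is not None and not (
            SOBP_WIDTH_BOUNDS_CM[0] <= self.sobp_width <= SOBP_WIDTH_BOUNDS_CM[1]
        ):
            raise SyntheticDataError(
                f"sobp_width {self.sobp_width} cm outside {SOBP_WIDTH_BOUNDS_CM}"
            )


@dataclass(frozen=True)
class SyntheticPlan:
    """Two opposed-lateral field dose grids plus aligned organ masks."""

    fields: tuple[DoseGrid, DoseGrid]
    masks: dict[str, StructureMask]
    parameters: dict = field(default_factory=dict)

    @property
    def ctv(self) -> StructureMask:
        return self.masks["ctv"]


def _ellipsoid_volume(semi_axes: Iterable[float]) -> float:
    a, b, c = semi_axes
    return 4.0 / 3.0 * np.pi * a * b * c


def _voxel_centers(shape, spacing):
    return [np.arange(n) * s for n, s in zip(shape, spacing)]


def _ellipsoid_mask(coords, center, semi_axes) -> np.ndarray:
    x, y, z = coords
    u = (x[:, None, None] - center[0]) / semi_axes[0]
    v = (y[None, :, None] - center[1]) / semi_axes[1]
    w = (z[None, None, :] - center[2]) / semi_axes[2]
    return u * u + v * v + w * w <= 1.0


def _flat_with_penumbra(coord, center, half_width, sigma):
    lo, hi = center - half_width, center + half_width
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((coord - lo) / s) - erf((coord - hi) / s))


def _depth_profile(depth, beam_range, sobp_width):
    """Entrance plateau (70%), SOBP plateau (100%), sigmoid distal falloff."""
    proximal = 0.7 + 0.3 * 0.5 * (1.0 + erf((depth - (beam_range - sobp_width)) / (0.4 * np.sqrt(2))))
    distal = 0.5 * (1.0 - erf((depth - beam_range) / (0.25 * np.sqrt(2))))
    return proximal * distal


def gen_plan(spec: SyntheticPlanSpec = SyntheticPlanSpec()) -> SyntheticPlan:
    """Generate an opposed-lateral two-field plan with pelvic organ masks.

    Fields enter from the patient's left and right (the x axis); masks are
    ellipsoids: CTV at the grid centre, bladder anterior-superior, rectum
    posterior (elongated inferior-superior), and two femoral-head spheres
    laterally.  Field grids are unnormalised (arbitrary dose scale); use
    :func:`protonplan.dosimetry.combine_fields` to impose the per-field CTV
    prescription.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing
    coords = _voxel_centers(shape, spacing)
    extent = [(n - 1) * s for n, s in zip(shape, spacing)]
    center = np.array([e / 2.0 for e in extent])

    # CTV geometry: sample semi-axes until the volume lands in the clinical
    # interval (explicit axes were validated by the spec already).
    if spec.ctv_semi_axes is not None:
        semi = np.asarray(spec.ctv_semi_axes, dtype=float)
    else:
        lo, hi = CTV_VOLUME_BOUNDS_CM3
        for _ in range(200):
            semi = np.array(
                [rng.uniform(2.2, 2.8), rng.uniform(1.9, 2.4), rng.uniform(1.9, 2.4)]
            )
            if lo <= _ellipsoid_volume(semi) <= hi:
                break
        else:  # pragma: no cover - interval is easily reachable
            raise SyntheticDataError("could not sample a CTV volume inside the bounds")

    masks_geo = {
        "ctv": (center, semi),
        "bladder": (center + np.array([0.0, -4.0, 1.0]), np.array([2.5, 2.0, 2.0])),
        "rectum": (center + np.array([0.0, 3.8, 0.0]), np.array([1.4, 1.4, 4.0])),
    }
    masks = {
        label: StructureMask(
            _ellipsoid_mask(coords, c, s), spacing=spacing, origin=(0, 0, 0), label=label
        )
        for label, (c, s) in masks_geo.items()
    }
    fem_r = 2.0
    fem = np.zeros(shape, dtype=bool)
    for side in (-1.0, 1.0):
        fem |= _ellipsoid_mask(
            coords, center + np.array([side * 7.0, 0.5, -1.0]), (fem_r, fem_r, fem_r)
        )
    masks["femoral_heads"] = StructureMask(
        fem, spacing=spacing, origin=(0, 0, 0), label="femoral_heads"
    )

    sigma = spec.penumbra_sigma * PLAN_VARIANTS[spec.variant]
    half_widths = (semi[1] + 0.8, semi[2] + 0.8)
    lat_y = _flat_with_penumbra(coords[1], center[1], half_widths[0], sigma)
    lat_z = _flat_with_penumbra(coords[2], center[2], half_widths[1], sigma)
    lateral = lat_y[None, :, None] * lat_z[None, None, :]

    fields = []
    ranges, widths = [], []
    for entering_from_low_x in (True, False):
        beam_range = (
            spec.beam_range
            if spec.beam_range is not None
            else rng.uniform(*BEAM_RANGE_BOUNDS_CM)
        )
        sobp_width = (
            spec.sobp_width
            if spec.sobp_width is not None
            else rng.uniform(*SOBP_WIDTH_BOUNDS_CM)
        )
        ranges.append(beam_range)
        widths.append(sobp_width)
        depth = coords[0] if entering_from_low_x else extent[0] - coords[0]
        # Planner's range choice: the beam stops 0.7 cm past the distal
        # (contralateral) CTV edge.  The sampled range is water-equivalent;
        # mapping it onto that geometric stopping depth sets the effective
        # tissue density of the phantom.
        geometric_stop = center[0] + semi[0] + 0.7
        wet_per_cm = beam_range / geometric_stop
        profile = _depth_profile(depth * wet_per_cm, beam_range, sobp_width)
        dose = profile[:, None, None] * lateral
        if spec.noise_amplitude > 0:
            dose = dose * (1.0 + spec.noise_amplitude * rng.standard_normal(shape))
        fields.append(DoseGrid(np.clip(dose, 0.0, None), spacing=spacing, origin=(0, 0, 0)))

    parameters = {
        "seed": spec.seed,
        "variant": spec.variant,
        "ctv_semi_axes_cm": tuple(float(s) for s in semi),
        "ctv_volume_cm3": float(_ellipsoid_volume(semi)),
        "beam_ranges_cm": tuple(ranges),
        "sobp_widths_cm": tuple(widths),
        "penumbra_sigma_cm": float(sigma),
    }
    return SyntheticPlan(fields=(fields[0], fields[1]), masks=masks, parameters=parameters)


@dataclass(frozen=True)
class SyntheticNeutronSpec:
    """Parameters of a paired SOC / MLC-only neutron organ-dose table.

    ``scales`` maps organ label -> (soc_external, soc_internal,
    mlc_external, mlc_internal) in mSv; unset, the published per-organ
    Monte Carlo values are used.  ``noise`` is the relative log-normal
    scatter applied per component.
    """

    seed: int = 0
    scales: dict[str, tuple[float, float, float, float]] | None = None
    noise: float = 0.05
    max_retries: int = 20

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise SyntheticDataError("noise must be non-negative")
        if self.max_retries < 1:
            raise SyntheticDataError("max_retries must be >= 1")
        if self.scales is not None:
            for organ, (es, is_, em, im) in self.scales.items():
                if min(es, is_, em, im) < 0:
                    raise SyntheticDataError(f"negative dose scale for organ {organ!r}")
                if not (em < es and im > is_):
                    raise SyntheticDataError(
                        f"scales for {organ!r} must satisfy MLC external < SOC external "
                        "and MLC internal > SOC internal"
                    )


def _default_neutron_scales() -> dict[str, tuple[float, float, float, float]]:
    soc = {d.organ: d for d in neutron_doses_soc()}
    mlc = {d.organ: d for d in neutron_doses_mlc_only()}
    return {
        organ: (soc[organ].external, soc[organ].internal, mlc[organ].external, mlc[organ].internal)
        for organ in soc
    }


def gen_neutron_table(
    spec: SyntheticNeutronSpec = SyntheticNeutronSpec(),
) -> tuple[list[OrganNeutronDose], list[OrganNeutronDose]]:
    """Generate a (SOC, MLC-only) pair of per-organ neutron dose tables.

    Totals are the exact sum of the external and internal components.  Each
    organ's noisy draw is resampled (up to ``max_retries``) until the MLC
    external component stays below the SOC one and the MLC internal stays
    above, the structural signature of swapping the custom aperture for an
    MLC; with ``noise=0`` the anchor values are returned unchanged.
    """
    rng = np.random.default_rng(spec.seed)
    scales = spec.scales if spec.scales is not None else _default_neutron_scales()
    soc_rows, mlc_rows = [], []
    for organ, (ext_soc, int_soc, ext_mlc, int_mlc) in scales.items():
        for attempt in range(spec.max_retries):
            if spec.noise == 0:
                draw = (ext_soc, int_soc, ext_mlc, int_mlc)
            else:
                factors = np.exp(spec.noise * rng.standard_normal(4))
                draw = (
                    ext_soc * factors[0],
                    int_soc * factors[1],
                    ext_mlc * factors[2],
                    int_mlc * factors[3],
                )
            if draw[2] < draw[0] and draw[3] > draw[1]:
                break
        else:
            raise SyntheticDataError(
                f"noise {spec.noise} violates the external/internal sign structure for "
                f"{organ!r} after {spec.max_retries} retries"
            )
        soc_rows.append(OrganNeutronDose(organ=organ, external=draw[0], internal=draw[1]))
        mlc_rows.append(OrganNeutronDose(organ=organ, external=draw[2], internal=draw[3]))
    return soc_rows, mlc_rows


def gen_aperture(
    seed: int = 0,
    mean_radius: float = 3.0,
    irregularity: float = 0.15,
    n_vertices: int = 96,
    n_harmonics: int = 5,
) -> AperturePolygon:
    """Draw a simple closed aperture outline around a circle of ``mean_radius``.

    The radius is perturbed by a random low-order Fourier series,
    ``r(theta) = R * (1 + sum_k a_k cos(k theta + phi_k))`` with harmonic
    amplitudes scaled by ``irregularity`` and damped as 1/k.  Star-shaped
    curves with positive radius are always simple, so amplitudes are capped
    to keep ``r > 0``; the resulting polygon is validated and resampled on
    the (unexpected) event of invalidity.
    """
    if mean_radius <= 0:
        raise SyntheticDataError(f"mean_radius must be positive, got {mean_radius}")
    if not 0 <= irregularity < 1:
        raise SyntheticDataError(f"irregularity must be in [0, 1), got {irregularity}")
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    for _ in range(10):
        radius = np.full_like(theta, 1.0)
        if irregularity > 0:
            amps = irregularity * rng.uniform(0.3, 1.0, n_harmonics) / np.arange(2, n_harmonics + 2)
            total = amps.sum()
            if total > 0.8:
                amps *= 0.8 / total
            phases = rng.uniform(0.0, 2.0 * np.pi, n_harmonics)
            for k, (a, phi) in enumerate(zip(amps, phases), start=2):
                radius += a * np.cos(k * theta + phi)
        radius *= mean_radius
        verts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        try:
            return AperturePolygon(verts)
        except ValueError:  # pragma: no cover - r > 0 keeps the curve simple
            continue
    raise SyntheticDataError("could not generate a simple aperture polygon")
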