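"""Neutron equivalent dose and lifetime second-cancer risk estimation.

Stray neutrons produced in the treatment head ("external") and inside the
patient ("internal") deposit dose far outside the treatment field.  The
absorbed neutron dose is weighted by a mean radiation weighting factor
(default 6.2, an average over external and internal neutron spectra) to give
an equivalent dose in Sv, and the lifetime attributable risk (LAR) of a
radiogenic second cancer in an organ is the product of the mean organ
equivalent dose and an organ-specific risk coefficient in %/Sv drawn from
BEIR VII-style epidemiologic models.

Default coefficients (60-year-old male): bladder 0.66 %/Sv, rectum
0.19 %/Sv.  The rectum value is a whole-colon coefficient scaled by a
fractional-mass correction of 0.2, since the rectum is roughly 20% of the
colon mass and applying the whole-colon coefficient to the near-field rectal
dose would overestimate risk.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "OrganNeutronDose",
    "NeutronWeighting",
    "RiskCoefficient",
    "RiskEstimate",
    "DoseTableComparison",
    "DEFAULT_RISK_COEFFICIENTS",
    "normalize_organ_label",
    "weight_neutron_dose",
    "derive_mass_corrected_coefficient",
    "organ_risk",
    "combined_risk",
    "compare_plan_doses",
    "load_organ_dose_table",
    "save_organ_dose_table",
    "neutron_doses_soc",
    "neutron_doses_mlc_only",
]


class RiskModelError(ValueError):
    """Raised for invalid doses, coefficients, or mismatched organ sets."""


#: Label synonyms mapped onto canonical snake_case organ names.
_LABEL_SYNONYMS = {
    "urinary_bladder": "bladder",
    "femoral_head": "femoral_heads",
    "clinical_target_volume": "ctv",
}


def normalize_organ_label(label: str) -> str:
    """Canonical organ key: lower case, underscores, synonyms folded."""
    key = "_".join(label.strip().lower().replace("-", " ").replace("/", " ").split())
    return _LABEL_SYNONYMS.get(key, key)


@dataclass(frozen=True)
class OrganNeutronDose:
    """Mean neutron equivalent dose to one organ, split by neutron origin.

    All values in mSv.  ``total`` may be given explicitly (printed tables are
    rounded per column, so external + internal can differ from the printed
    total by up to 1 mSv); if omitted it is the exact sum.
    """

    organ: str
    external: float
    internal: float
    total: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.external < 0 or self.internal < 0:
            raise RiskModelError(f"negative dose component for organ {self.organ!r}")
        if self.total is None:
            object.__setattr__(self, "total", self.external + self.internal)
        else:
            if self.total < 0:
                raise RiskModelError(f"negative total dose for organ {self.organ!r}")
            if abs(self.total - (self.external + self.internal)) > 1.0:
                raise RiskModelError(
                    f"total {self.total} mSv for {self.organ!r} differs from "
                    f"external+internal {self.external + self.internal} mSv by more than 1 mSv"
                )

    @property
    def key(self) -> str:
        return normalize_organ_label(self.organ)


@dataclass(frozen=True)
class NeutronWeighting:
    """Mean radiation weighting factor for neutrons (dimensionless)."""

    w_bar: float = 6.2

    def __post_init__(self) -> None:
        if self.w_bar <= 0:
            raise RiskModelError(f"weighting factor must be positive, got {self.w_bar}")


@dataclass(frozen=True)
class RiskCoefficient:
    """Lifetime-attributable-risk coefficient for one organ, in % per Sv.

    ``mass_fraction`` records any fractional-mass correction already applied
    to ``lar`` (1.0 means none); it is informational once applied.
    """

    organ: str
    lar: float
    mass_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.lar < 0:
            raise RiskModelError(f"LAR coefficient must be non-negative, got {self.lar}")
        if not 0 < self.mass_fraction <= 1:
            raise RiskModelError(f"mass_fraction must be in (0, 1], got {self.mass_fraction}")

    @property
    def key(self) -> str:
        return normalize_organ_label(self.organ)


#: Bladder and rectum are the only organs with built-in coefficients; the
#: rectum value is the whole-colon LAR after the 0.2 mass correction.
DEFAULT_RISK_COEFFICIENTS: dict[str, RiskCoefficient] = {
    "bladder": RiskCoefficient("bladder", lar=0.66),
    "rectum": RiskCoefficient("rectum", lar=0.19, mass_fraction=0.2),
}


@dataclass(frozen=True)
class RiskEstimate:
    """Predicted lifetime second-cancer incidence for one organ."""

    organ: str
    risk: float  # % lifetime incidence
    dose_used: float  # Sv


def weight_neutron_dose(absorbed_gy: float, w: NeutronWeighting = NeutronWeighting()) -> float:
    """Equivalent dose (Sv) from absorbed neutron dose (Gy)."""
    if absorbed_gy < 0:
        raise RiskModelError(f"absorbed dose must be non-negative, got {absorbed_gy}")
    return absorbed_gy * w.w_bar


def derive_mass_corrected_coefficient(whole_organ_lar: float, mass_fraction: float) -> float:
    """Scale a whole-organ LAR coefficient by the mass fraction of a sub-organ.

    E.g. a whole-colon coefficient of 0.95 %/Sv scaled by the rectum's 0.2
    mass fraction gives the 0.19 %/Sv rectal coefficient.
    """
    if whole_organ_lar < 0:
        raise RiskModelError(f"LAR must be non-negative, got {whole_organ_lar}")
    if not 0 < mass_fraction <= 1:
        raise RiskModelError(f"mass_fraction must be in (0, 1], got {mass_fraction}")
    return whole_organ_lar * mass_fraction


def organ_risk(dose: OrganNeutronDose, coeff: RiskCoefficient) -> RiskEstimate:
    """Lifetime risk (%) = mean organ equivalent dose (Sv) x LAR (%/Sv)."""
    if dose.key != coeff.key:
        raise RiskModelError(
            f"organ mismatch: dose for {dose.organ!r}, coefficient for {coeff.organ!r}"
        )
    dose_sv = dose.total / 1000.0
    return RiskEstimate(organ=dose.key, risk=dose_sv * coeff.lar, dose_used=dose_sv)


def _index_doses(table: Iterable[OrganNeutronDose]) -> dict[str, OrganNeutronDose]:
    return {d.key: d for d in table}


def combined_risk(
    table: Iterable[OrganNeutronDose],
    coeffs: Mapping[str, RiskCoefficient] | Sequence[RiskCoefficient] | None = None,
    organs: Sequence[str] = ("bladder", "rectum"),
    decimals: int | None = 2,
) -> float:
    """Summed lifetime risk (%) over the requested organs.

    Defaults to bladder + rectum with the built-in coefficients, rounded to
    two decimals; pass ``decimals=None`` for the raw sum.
    """
    doses = _index_doses(table)
    if coeffs is None:
        coeff_map = dict(DEFAULT_RISK_COEFFICIENTS)
    elif isinstance(coeffs, Mapping):
        coeff_map = {normalize_organ_label(k): v for k, v in coeffs.items()}
    else:
        coeff_map = {c.key: c for c in coeffs}
    total = 0.0
    for organ in organs:
        key = normalize_organ_label(organ)
        if key not in doses:
            raise RiskModelError(f"organ {organ!r} missing from the dose table")
        if key not in coeff_map:
            raise RiskModelError(f"no risk coefficient for organ {organ!r}")
        total += organ_risk(doses[key], replace(coeff_map[key], organ=key)).risk
    return round(total, decimals) if decimals is not None else total


class DoseTableComparison(NamedTuple):
    """Per-organ neutron-dose differences between two plans (b - a), mSv."""

    delta_external: dict[str, float]
    delta_internal: dict[str, float]
    delta_total: dict[str, float]
    max_abs_total_delta: float


def compare_plan_doses(
    table_a: Iterable[OrganNeutronDose], table_b: Iterable[OrganNeutronDose]
) -> DoseTableComparison:
    """Signed per-organ dose differences (b - a) and the max |total| delta."""
    a, b = _index_doses(table_a), _index_doses(table_b)
    if set(a) != set(b):
        raise RiskModelError(
            f"organ sets differ: only in a: {sorted(set(a) - set(b))}, "
            f"only in b: {sorted(set(b) - set(a))}"
        )
    d_ext = {k: b[k].external - a[k].external for k in a}
    d_int = {k: b[k].internal - a[k].internal for k in a}
    d_tot = {k: b[k].total - a[k].total for k in a}
    return DoseTableComparison(
        delta_external=d_ext,
        delta_internal=d_int,
        delta_total=d_tot,
        max_abs_total_delta=max(abs(v) for v in d_tot.values()),
    )


def load_organ_dose_table(path) -> list[OrganNeutronDose]:
    """Read an organ-dose table CSV (``organ,external_mSv,internal_mSv,total_mSv``)."""
    frame = pd.read_csv(path)
    required = {"organ", "external_mSv", "internal_mSv"}
    if not required.issubset(frame.columns):
        raise RiskModelError(f"missing columns: {sorted(required - set(frame.columns))}")
    rows = []
    for rec in frame.to_dict("records"):
        total = rec.get("total_mSv")
        rows.append(
            OrganNeutronDose(
                organ=str(rec["organ"]),
                external=float(rec["external_mSv"]),
                internal=float(rec["internal_mSv"]),
                total=None if total is None or pd.isna(total) else float(total),
            )
        )
    return rows


def save_organ_dose_table(table: Iterable[OrganNeutronDose], path) -> None:
    """Write an organ-dose table in the CSV layout read by :func:`load_organ_dose_table`."""
    pd.DataFrame(
        [
            {
                "organ": d.organ,
                "external_mSv": d.external,
                "internal_mSv": d.internal,
                "total_mSv": d.total,
            }
            for d in table
        ]
    ).to_csv(path, index=False)


def _packaged_table(name: str) -> list[OrganNeutronDose]:
    with resources.files("protonplan.data").joinpath(name).open() as handle:
        return load_organ_dose_table(handle)


def neutron_doses_soc() -> list[OrganNeutronDose]:
    """Packaged per-organ neutron doses for the standard-of-care plan (one patient)."""
    return _packaged_table("neutron_doses_soc.csv")


def neutron_doses_mlc_only() -> list[OrganNeutronDose]:
    """Packaged per-organ neutron doses for the MLC-only plan (same patient)."""
    return _packaged_table("neutron_doses_mlc_only.csv")
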