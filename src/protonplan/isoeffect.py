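"""Linear-quadratic isoeffect conversion between fractionation regimens.

The linear-quadratic (LQ) model assigns a biologically effective dose

    BED = D * (1 + d / (alpha/beta))

to a regimen delivering total dose ``D`` in fractions of size ``d``.  Two
regimens with equal BED are isoeffective for a tissue characterised by the
ratio alpha/beta (Gy), which sets the sensitivity to fraction size.  Prostate
tumours are believed to have a low alpha/beta (roughly 1-5 Gy), which is the
rationale for hypofractionation: fewer, larger fractions at a lower total
dose can match the tumour effect of a conventional schedule.

Given a target fraction count ``n``, the isoeffective photon total dose is
the positive root of ``n*(D/n)*(1 + (D/n)/(alpha/beta)) = BED``:

    D(n) = (n/2) * (alpha/beta) * (-1 + sqrt(1 + 4*BED / (n*(alpha/beta))))

Proton prescriptions are expressed in absorbed dose; with the generic
clinical relative biological effectiveness (RBE) of 1.1, the proton absorbed
dose that matches a photon dose is the photon dose divided by the RBE (the
tabulated proton dose times ~1.1 recovers the photon-equivalent dose in
Gy (RBE)).

The module builds hypofractionation equivalence tables bracketing the
alpha/beta uncertainty (canonically {1, 3, 5} Gy) and quantifies the
prescription uncertainty as the max/min ratio of the bracketed total doses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

__all__ = [
    "Regimen",
    "LQParameters",
    "BEDValue",
    "RBEModel",
    "EquivalenceRow",
    "UncertaintyAssessment",
    "CANONICAL_ALPHA_BETA",
    "DEFAULT_N_GRID",
    "DEFAULT_SIGNIFICANCE_BAND",
    "REFERENCE_PHOTON_REGIMEN",
    "bed_gray",
    "compute_bed",
    "isoeffective_total_dose",
    "photon_to_proton_dose",
    "equivalence_table",
    "uncertainty_ratio",
    "table_to_frame",
]

#: alpha/beta bracket (Gy) conventionally used for prostate tumours.
CANONICAL_ALPHA_BETA: tuple[float, ...] = (1.0, 3.0, 5.0)

#: Fraction-count grid used for the default equivalence table.
DEFAULT_N_GRID: tuple[int, ...] = (1, 3, 5, 10, 15, 20, 25, 30, 35, 38, 40, 44, 45)

#: Ratios above the upper edge are clinically significant; ratios inside the
#: band are borderline (comparable in magnitude to dose-delivery errors).
DEFAULT_SIGNIFICANCE_BAND: tuple[float, float] = (1.05, 1.10)


class IsoeffectError(ValueError):
    """Raised for invalid regimens, parameters, or mismatched alpha/beta."""


@dataclass(frozen=True)
class Regimen:
    """A fractionation prescription: total dose, fraction count, fraction size.

    ``fraction_size`` may be omitted, in which case it is derived as
    ``total_dose / n_fractions``.  When given explicitly it must be
    consistent with the other two fields to 1e-9 relative.
    """

    total_dose: float
    n_fractions: int
    fraction_size: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.total_dose <= 0:
            raise IsoeffectError(f"total_dose must be positive, got {self.total_dose}")
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise IsoeffectError(f"n_fractions must be a positive integer, got {self.n_fractions}")
        if self.fraction_size is None:
            object.__setattr__(self, "fraction_size", self.total_dose / self.n_fractions)
        else:
            if self.fraction_size <= 0:
                raise IsoeffectError(f"fraction_size must be positive, got {self.fraction_size}")
            if not math.isclose(
                self.total_dose, self.n_fractions * self.fraction_size, rel_tol=1e-9
            ):
                raise IsoeffectError(
                    f"inconsistent regimen: {self.n_fractions} x {self.fraction_size} Gy "
                    f"!= {self.total_dose} Gy"
                )


#: Conventional photon standard of care for prostate: 79.2 Gy in 44 fractions.
REFERENCE_PHOTON_REGIMEN = Regimen(79.2, 44)


@dataclass(frozen=True)
class LQParameters:
    """LQ fraction-size sensitivity parameter alpha/beta in Gy."""

    alpha_beta: float

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise IsoeffectError(f"alpha/beta must be positive, got {self.alpha_beta}")


@dataclass(frozen=True)
class BEDValue:
    """A biologically effective dose together with the alpha/beta that produced it."""

    bed: float
    alpha_beta_used: float


@dataclass(frozen=True)
class RBEModel:
    """Constant proton RBE model (generic clinical value 1.1)."""

    rbe: float = 1.1

    def __post_init__(self) -> None:
        if self.rbe <= 0:
            raise IsoeffectError(f"RBE must be positive, got {self.rbe}")
        if self.rbe < 1.0:
            raise IsoeffectError(f"constant-RBE model requires RBE >= 1, got {self.rbe}")


def bed_gray(total_dose: float, fraction_size: float, alpha_beta: float) -> float:
    """BED in Gy for a total dose delivered in fractions of the given size.

    ``fraction_size = 0`` is accepted as the low-dose-per-fraction limit, in
    which BED equals the physical dose.
    """
    if total_dose < 0:
        raise IsoeffectError(f"total_dose must be non-negative, got {total_dose}")
    if fraction_size < 0:
        raise IsoeffectError(f"fraction_size must be non-negative, got {fraction_size}")
    if alpha_beta <= 0:
        raise IsoeffectError(f"alpha/beta must be positive, got {alpha_beta}")
    return total_dose * (1.0 + fraction_size / alpha_beta)


def compute_bed(regimen: Regimen, lq: LQParameters) -> BEDValue:
    """BED of a regimen under the given LQ parameters."""
    return BEDValue(
        bed=bed_gray(regimen.total_dose, regimen.fraction_size, lq.alpha_beta),
        alpha_beta_used=lq.alpha_beta,
    )


def isoeffective_total_dose(n: int, bed: BEDValue, lq: LQParameters) -> float:
    """Photon total dose in ``n`` fractions isoeffective with ``bed``.

    Returns the positive root of ``n*d*(1 + d/(alpha/beta)) = BED`` scaled to
    a total dose.  The BED must have been computed with the same alpha/beta
    as ``lq``; mixing alpha/beta values silently would not be an isoeffect
    statement, so it is rejected.
    """
    if int(n) != n or n < 1:
        raise IsoeffectError(f"n must be a positive integer, got {n}")
    if not math.isclose(bed.alpha_beta_used, lq.alpha_beta, rel_tol=1e-12):
        raise IsoeffectError(
            f"alpha/beta mismatch: BED computed at {bed.alpha_beta_used} Gy, "
            f"requested {lq.alpha_beta} Gy"
        )
    ab = lq.alpha_beta
    discriminant = 1.0 + 4.0 * bed.bed / (n * ab)
    assert discriminant > 0.0  # impossible to violate for positive inputs
    return 0.5 * n * ab * (-1.0 + math.sqrt(discriminant))


def photon_to_proton_dose(photon_dose: float, rbe: RBEModel = RBEModel()) -> float:
    """Proton absorbed dose (Gy) matching a photon dose under constant RBE.

    The proton prescription is the photon dose divided by the RBE; multiplying
    the proton dose by the RBE recovers the photon-equivalent dose in Gy (RBE).
    """
    if photon_dose < 0:
        raise IsoeffectError(f"photon_dose must be non-negative, got {photon_dose}")
    return photon_dose / rbe.rbe


class UncertaintyAssessment(NamedTuple):
    ratio: float
    clinically_significant: bool
    borderline: bool


def uncertainty_ratio(
    totals: Mapping[float, float] | Iterable[float],
    significance_band: tuple[float, float] = DEFAULT_SIGNIFICANCE_BAND,
) -> UncertaintyAssessment:
    """Max/min ratio over bracketed total doses and its clinical reading.

    The ratio measures the prescription uncertainty due to the alpha/beta
    bracket.  Ratios above the upper band edge are flagged clinically
    significant; ratios inside the band are borderline (comparable to
    dose-delivery errors).
    """
    values = list(totals.values()) if isinstance(totals, Mapping) else list(totals)
    if len(values) < 2:
        raise IsoeffectError("at least two totals are required for a ratio")
    if any(v <= 0 for v in values):
        raise IsoeffectError("all totals must be positive")
    lower, upper = significance_band
    if not 1.0 <= lower <= upper:
        raise IsoeffectError(f"invalid significance band {significance_band}")
    ratio = max(values) / min(values)
    return UncertaintyAssessment(
        ratio=ratio,
        clinically_significant=ratio > upper,
        borderline=lower < ratio <= upper,
    )


@dataclass(frozen=True)
class EquivalenceRow:
    """One line of a hypofractionation equivalence table.

    Doses are unrounded proton absorbed doses (Gy) keyed by alpha/beta;
    rounding to the presentation convention happens in :func:`table_to_frame`.
    """

    n_fractions: int
    fraction_size_by_ab: dict[float, float]
    total_dose_by_ab: dict[float, float]
    ratio_max_min: float
    clinically_significant: bool
    borderline: bool

    def sorted_totals(self) -> list[float]:
        """Totals in ascending order (min, mid, max presentation columns)."""
        return sorted(self.total_dose_by_ab.values())


def equivalence_table(
    reference: Regimen = REFERENCE_PHOTON_REGIMEN,
    ab_values: Sequence[float] = CANONICAL_ALPHA_BETA,
    n_grid: Sequence[int] = DEFAULT_N_GRID,
    rbe: RBEModel = RBEModel(),
    significance_band: tuple[float, float] = DEFAULT_SIGNIFICANCE_BAND,
) -> list[EquivalenceRow]:
    """Proton prescriptions isoeffective with a photon reference regimen.

    For each fraction count ``n`` and each alpha/beta in the bracket, the
    photon total dose isoeffective with the reference is computed from the
    reference BED and converted to proton absorbed dose via the RBE.  The
    max/min ratio over the bracket is computed from unrounded totals.

    Note that below the reference fraction size the lowest alpha/beta gives
    the lowest equivalent dose, while above it the ordering flips; presenting
    rows as (min, mid, max) therefore refers to sorted values, which
    coincide with ascending alpha/beta only for hypofractionated rows.
    """
    if not ab_values:
        raise IsoeffectError("ab_values must be non-empty")
    if not n_grid:
        raise IsoeffectError("n_grid must be non-empty")
    rows: list[EquivalenceRow] = []
    for n in sorted(set(int(n) for n in n_grid)):
        totals: dict[float, float] = {}
        fracs: dict[float, float] = {}
        for ab in ab_values:
            lq = LQParameters(ab)
            bed = compute_bed(reference, lq)
            photon_total = isoeffective_total_dose(n, bed, lq)
            proton_total = photon_to_proton_dose(photon_total, rbe)
            totals[ab] = proton_total
            fracs[ab] = proton_total / n
        if len(totals) == 1:  # a single alpha/beta carries no bracket uncertainty
            assessment = UncertaintyAssessment(1.0, False, False)
        else:
            assessment = uncertainty_ratio(totals, significance_band)
        rows.append(
            EquivalenceRow(
                n_fractions=n,
                fraction_size_by_ab=fracs,
                total_dose_by_ab=totals,
                ratio_max_min=assessment.ratio,
                clinically_significant=assessment.clinically_significant,
                borderline=assessment.borderline,
            )
        )
    return rows


def table_to_frame(rows: Sequence[EquivalenceRow]):
    """Equivalence rows as a DataFrame in the conventional presentation.

    Columns ``frac_*`` / ``total_*`` are the sorted bracket values rounded to
    one decimal; ``ratio`` is rounded to two decimals.  All rounding happens
    here, from unrounded values.
    """
    import pandas as pd

    records = []
    for row in rows:
        totals = row.sorted_totals()
        fracs = [t / row.n_fractions for t in totals]
        records.append(
            {
                "n": row.n_fractions,
                "frac_min": round(fracs[0], 1),
                "frac_mid": round(fracs[len(fracs) // 2], 1),
                "frac_max": round(fracs[-1], 1),
                "total_min": round(totals[0], 1),
                "total_mid": round(totals[len(totals) // 2], 1),
                "total_max": round(totals[-1], 1),
                "ratio": round(row.ratio_max_min, 2),
            }
        )
    return pd.DataFrame.from_records(records)
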