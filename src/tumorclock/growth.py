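"""Core exponential-growth arithmetic.

A tumor is modelled as a sphere growing from a single founder cell by
repeated volume doublings: each doubling multiplies the volume by 2 and the
diameter by 2^(1/3).  Every conversion here is a pure function of the
doubling count ``n``::

    diameter(n)   = founder_diameter * 2^(n/3)
    cell_count(n) = 2^n
    volume(d)     = pi * d^3 / 6

The doubling time (TVDT) of an individual tumor is estimated from two dated
diameter measurements with the classical two-point volume estimator
(Schwartz): ``tvdt = delta_t * ln2 / (ln V1 - ln V0)``, which in diameter
form is ``delta_t / (3 * log2(d1/d0))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ChronologyError, GrowthDomainError, NonGrowthError

__all__ = [
    "ModelConstants",
    "GrowthState",
    "MeasurementPair",
    "DEFAULT_CONSTANTS",
    "doublings_from_diameter",
    "diameter_from_doublings",
    "cell_count_from_doublings",
    "volume_from_diameter",
    "schwartz_doubling_time",
]


@dataclass(frozen=True)
class ModelConstants:
    """Fixed parameters of the shared doubling clock.

    Defaults: a 10 um founder cell, distant metastasis seeded at the primary
    tumor's 20th doubling (diameter 1 mm, ~10^6 cells), death when the
    metastasis completes the remaining 40 doublings of the 60-doubling clock
    (~103 mm), primary visible above 1 mm and a metastasis clinically
    detectable above 9 mm.
    """

    founder_diameter_mm: float = 0.01
    seeding_doubling: float = 20.0
    lethal_total_doublings: float = 60.0
    pt_visible_diameter_mm: float = 1.0
    mts_visible_diameter_mm: float = 9.0
    days_per_year: float = 365.25

    def __post_init__(self) -> None:
        for name in (
            "founder_diameter_mm",
            "seeding_doubling",
            "lethal_total_doublings",
            "pt_visible_diameter_mm",
            "mts_visible_diameter_mm",
            "days_per_year",
        ):
            if getattr(self, name) <= 0:
                raise GrowthDomainError(f"{name} must be strictly positive")
        if self.seeding_doubling >= self.lethal_total_doublings:
            raise GrowthDomainError(
                "seeding_doubling must be below lethal_total_doublings"
            )
        lethal_d = self.founder_diameter_mm * 2.0 ** (
            self.lethal_total_doublings / 3.0
        )
        if not (
            self.pt_visible_diameter_mm
            < self.mts_visible_diameter_mm
            < lethal_d
        ):
            raise GrowthDomainError(
                "visibility thresholds must satisfy "
                "pt_visible < mts_visible < lethal diameter"
            )


DEFAULT_CONSTANTS = ModelConstants()


def doublings_from_diameter(
    d_mm: float, constants: ModelConstants = DEFAULT_CONSTANTS
) -> float:
    """Volume doublings needed to grow the founder cell to diameter ``d_mm``.

    Inverse of :func:`diameter_from_doublings`:
    ``n = 3 * log2(d / founder_diameter)``.
    """
    if d_mm <= 0:
        raise GrowthDomainError("diameter must be strictly positive")
    if d_mm < constants.founder_diameter_mm:
        raise GrowthDomainError(
            f"diameter {d_mm} mm is below the founder-cell diameter "
            f"({constants.founder_diameter_mm} mm)"
        )
    return 3.0 * math.log2(d_mm / constants.founder_diameter_mm)


def diameter_from_doublings(
    n: float, constants: ModelConstants = DEFAULT_CONSTANTS
) -> float:
    """Diameter (mm) after ``n`` volume doublings of the founder cell."""
    if n < 0:
        raise GrowthDomainError("doubling count must be nonnegative")
    return constants.founder_diameter_mm * 2.0 ** (n / 3.0)


def cell_count_from_doublings(n: float) -> float:
    """Cell count after ``n`` volume doublings of a single founder cell."""
    if n < 0:
        raise GrowthDomainError("doubling count must be nonnegative")
    return 2.0**n


def volume_from_diameter(d_mm: float) -> float:
    """Spherical volume (mm^3) of a tumor of diameter ``d_mm``."""
    if d_mm <= 0:
        raise GrowthDomainError("diameter must be strictly positive")
    return math.pi * d_mm**3 / 6.0


@dataclass(frozen=True)
class GrowthState:
    """A tumor at one instant: doubling count, diameter and cell count."""

    doublings: float
    diameter_mm: float
    cell_count: float

    @classmethod
    def from_doublings(
        cls, n: float, constants: ModelConstants = DEFAULT_CONSTANTS
    ) -> "GrowthState":
        return cls(
            doublings=n,
            diameter_mm=diameter_from_doublings(n, constants),
            cell_count=cell_count_from_doublings(n),
        )

    @classmethod
    def from_diameter(
        cls, d_mm: float, constants: ModelConstants = DEFAULT_CONSTANTS
    ) -> "GrowthState":
        n = doublings_from_diameter(d_mm, constants)
        return cls(doublings=n, diameter_mm=d_mm, cell_count=cell_count_from_doublings(n))


@dataclass(frozen=True)
class MeasurementPair:
    """Two dated diameter measurements of the same lesion.

    ``delta_days`` is the elapsed time from the first to the second
    measurement; growth (``d1 > d0``) is required for the estimator.
    """

    d0_mm: float
    d1_mm: float
    delta_days: float

    def __post_init__(self) -> None:
        if self.d0_mm <= 0 or self.d1_mm <= 0:
            raise GrowthDomainError("diameters must be strictly positive")
        if self.delta_days <= 0:
            raise ChronologyError(
                "second measurement must be strictly later than the first"
            )
        if self.d1_mm <= self.d0_mm:
            raise NonGrowthError(
                "no growth between measurements "
                f"(d0={self.d0_mm} mm, d1={self.d1_mm} mm); "
                "doubling time is undefined"
            )


def schwartz_doubling_time(pair: MeasurementPair) -> float:
    """Tumor volume doubling time (days) from two diameter measurements.

    ``tvdt = delta_t * ln2 / (ln V1 - ln V0) = delta_t / (3 * log2(d1/d0))``.
    The diameter form is used directly; it is algebraically identical to the
    volume form for spherical lesions and base-independent.
    """
    return pair.delta_days / (3.0 * math.log2(pair.d1_mm / pair.d0_mm))
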