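"""Prognosis and relapse-risk classification from the computed timeline.

Both classifiers key on the occult post-surgery metastasis period (the time
from surgery until the first distant metastasis becomes clinically
detectable): a longer occult period means a later relapse and a better
forecast.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import GrowthDomainError
from .natural_history import NaturalHistoryTimeline

__all__ = [
    "PrognosisClass",
    "RiskGroup",
    "classify_prognosis",
    "risk_group",
    "classify_timeline",
]


@dataclass(frozen=True)
class PrognosisClass:
    """Life-forecast band: favourable (> 5 y), moderately favourable [3, 5],
    unfavourable (< 3 y)."""

    label: str
    basis_years: float


@dataclass(frozen=True)
class RiskGroup:
    """Relapse-risk window: high [0, 5), medium [5, 10), low [10, inf)."""

    label: str
    window_years: tuple[float, float]


_RISK_WINDOWS = (
    ("high", (0.0, 5.0)),
    ("medium", (5.0, 10.0)),
    ("low", (10.0, float("inf"))),
)


def classify_prognosis(first_mts_period_years: float) -> PrognosisClass:
    """Forecast band from the post-surgery occult metastasis period (years).

    Strictly more than five years is favourable; three to five years
    inclusive is moderately favourable; under three years is unfavourable.
    """
    y = first_mts_period_years
    if y < 0:
        raise GrowthDomainError("period must be nonnegative")
    if y > 5.0:
        label = "favourable"
    elif y >= 3.0:
        label = "moderately_favourable"
    else:
        label = "unfavourable"
    return PrognosisClass(label=label, basis_years=y)


def risk_group(first_mts_period_years: float) -> RiskGroup:
    """Relapse-risk group from the post-surgery occult metastasis period."""
    y = first_mts_period_years
    if y < 0:
        raise GrowthDomainError("period must be nonnegative")
    for label, (lo, hi) in _RISK_WINDOWS:
        if lo <= y < hi:
            return RiskGroup(label=label, window_years=(lo, hi))
    raise AssertionError("risk windows cover [0, inf)")  # pragma: no cover


def classify_timeline(
    timeline: NaturalHistoryTimeline,
) -> tuple[PrognosisClass, RiskGroup]:
    """Classify a patient timeline using its occult post-surgery MTS period."""
    period = timeline.nonvisible_mts2_years
    return classify_prognosis(period), risk_group(period)
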