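"""Timeline decomposition of the whole natural history on the 60-doubling clock.

The primary tumor (PT) grows exponentially from a single founder cell; at the
seeding doubling (20th by default, diameter 1 mm) it sheds the first distant
metastasis (MTS) cell, which grows at the same volume-doubling rate (scaled
by ``k_smts``).  Death occurs when the MTS completes the clock, i.e. reaches
``lethal_total_doublings - seeding_doubling`` doublings (~103 mm by default).

With ``n_s`` PT doublings at surgery, PT doubling time ``tvdt`` and MTS
doubling time ``tvdt / k_smts``, the decomposition is:

==================  =====================================================
non-visible PT      growth below the 1 mm PT threshold
visible PT          1 mm threshold -> surgery
non-visible MTS-I   MTS seeding -> surgery (~ visible PT for k = 1)
non-visible MTS-II  surgery -> MTS reaches its 9 mm detection threshold
visible MTS         MTS detection threshold -> lethal size
survival            surgery -> death (non-visible MTS-II + visible MTS)
==================  =====================================================

The four disjoint segments (non-visible PT, visible PT, non-visible MTS-II,
visible MTS) tile the whole natural history exactly.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import asdict, dataclass, field

from .errors import GrowthDomainError, PastLethalError
from .growth import (
    DEFAULT_CONSTANTS,
    ModelConstants,
    diameter_from_doublings,
    doublings_from_diameter,
)
from .staging import StageParameters, classify_t_stage, stage_parameters

__all__ = [
    "NaturalHistoryTimeline",
    "TimelineEvents",
    "compute_timeline",
    "timeline_for_diameter",
    "anchor_events",
    "growth_curve",
]


@dataclass(frozen=True)
class NaturalHistoryTimeline:
    """Full period decomposition for one patient (all periods in years)."""

    d_surgery_mm: float
    tvdt_days: float
    pt_doublings_at_surgery: float
    mts_doublings_at_surgery: float
    mts_diameter_at_surgery_mm: float
    wnh_years: float
    total_pt_years: float
    nonvisible_pt_years: float
    visible_pt_years: float
    nonvisible_mts1_years: float
    nonvisible_mts2_years: float
    visible_mts_years: float
    survival_years: float
    mts_seeded: bool = True
    mts_manifest_at_surgery: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TimelineEvents:
    """Calendar anchoring of the timeline around a surgery date.

    Events are strictly ordered: first PT cell < PT visible <= MTS seeded
    <= surgery < MTS visible < lethal endpoint.
    """

    first_pt_cell: _dt.date
    pt_visible: _dt.date
    mts_seeded: _dt.date
    surgery: _dt.date
    mts_visible: _dt.date
    lethal: _dt.date

    def ordered(self) -> list[tuple[str, _dt.date]]:
        return [
            ("first_pt_cell", self.first_pt_cell),
            ("pt_visible", self.pt_visible),
            ("mts_seeded", self.mts_seeded),
            ("surgery", self.surgery),
            ("mts_visible", self.mts_visible),
            ("lethal", self.lethal),
        ]


def compute_timeline(
    d_surgery_mm: float,
    params: StageParameters,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> NaturalHistoryTimeline:
    """Decompose the whole natural history for a pre-surgery PT diameter.

    Raises :class:`PastLethalError` if the PT alone has already exceeded the
    60-doubling clock.  For diameters below the seeding size the MTS fields
    are zero and ``mts_seeded`` is False.
    """
    c = constants
    n_s = doublings_from_diameter(d_surgery_mm, c)
    if n_s > c.lethal_total_doublings:
        raise PastLethalError(
            f"diameter {d_surgery_mm} mm corresponds to {n_s:.1f} doublings, "
            f"beyond the {c.lethal_total_doublings:.0f}-doubling lethal clock"
        )
    tvdt = params.tvdt_days
    tau_mts = tvdt / params.k_smts
    per_year = c.days_per_year

    n_seed = c.seeding_doubling
    n_pvis = doublings_from_diameter(c.pt_visible_diameter_mm, c)
    n_mvis = doublings_from_diameter(c.mts_visible_diameter_mm, c)

    # The PT occult/visible split sits at the 1 mm visibility threshold
    # (19.93 doublings), while the MTS clock starts at the seeding doubling
    # (exactly 20, i.e. 1.016 mm).  The two nearly coincide but are distinct;
    # only this pairing reproduces every published period.
    nonvisible_pt = min(n_s, n_pvis) * tvdt
    visible_pt = max(n_s - n_pvis, 0.0) * tvdt
    total_pt = n_s * tvdt
    wnh = c.lethal_total_doublings * tvdt

    # the first MTS cell is shed once the PT reaches its visibility size
    mts_seeded = d_surgery_mm >= c.pt_visible_diameter_mm
    if mts_seeded:
        # reported MTS state clamps at zero in the 1 mm boundary sliver
        # where surgery precedes the exact seeding doubling
        n_mts = max(n_s - n_seed, 0.0)
        mts_d = diameter_from_doublings(n_mts, c)
        nonvisible_mts1 = n_mts * tau_mts
        # calendar period surgery -> MTS detectable; deliberately unclamped
        # below the seeding doubling so the four segments tile the history
        nonvisible_mts2 = (n_mvis - (n_s - n_seed)) * tau_mts
        visible_mts = ((c.lethal_total_doublings - n_seed) - n_mvis) * tau_mts
        manifest = nonvisible_mts2 < 0
        if manifest:
            # MTS already clinically detectable at surgery: fold the
            # negative occult period into the visible one.
            visible_mts += nonvisible_mts2
            nonvisible_mts2 = 0.0
        survival = nonvisible_mts2 + visible_mts
    else:
        n_mts = 0.0
        mts_d = 0.0
        nonvisible_mts1 = nonvisible_mts2 = visible_mts = survival = 0.0
        manifest = False

    return NaturalHistoryTimeline(
        d_surgery_mm=d_surgery_mm,
        tvdt_days=tvdt,
        pt_doublings_at_surgery=n_s,
        mts_doublings_at_surgery=n_mts,
        mts_diameter_at_surgery_mm=mts_d,
        wnh_years=wnh / per_year,
        total_pt_years=total_pt / per_year,
        nonvisible_pt_years=nonvisible_pt / per_year,
        visible_pt_years=visible_pt / per_year,
        nonvisible_mts1_years=nonvisible_mts1 / per_year,
        nonvisible_mts2_years=nonvisible_mts2 / per_year,
        visible_mts_years=visible_mts / per_year,
        survival_years=survival / per_year,
        mts_seeded=mts_seeded,
        mts_manifest_at_surgery=manifest,
    )


def timeline_for_diameter(
    d_surgery_mm: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    nodal_status: str = "N0",
) -> NaturalHistoryTimeline:
    """Classify the stage from diameter, then compute the timeline."""
    stage = classify_t_stage(d_surgery_mm)
    params = stage_parameters(stage, nodal_status)
    return compute_timeline(d_surgery_mm, params, constants)


def _shift(date: _dt.date, days: float) -> _dt.date:
    return date + _dt.timedelta(days=days)


def anchor_events(
    timeline: NaturalHistoryTimeline,
    surgery_date: _dt.date,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> TimelineEvents:
    """Place the timeline's milestones on the calendar around a surgery date."""
    if not timeline.mts_seeded:
        raise GrowthDomainError(
            "cannot anchor MTS events: metastasis not yet seeded at surgery"
        )
    per_year = constants.days_per_year
    return TimelineEvents(
        first_pt_cell=_shift(surgery_date, -timeline.total_pt_years * per_year),
        pt_visible=_shift(surgery_date, -timeline.visible_pt_years * per_year),
        mts_seeded=_shift(surgery_date, -timeline.nonvisible_mts1_years * per_year),
        surgery=surgery_date,
        mts_visible=_shift(surgery_date, timeline.nonvisible_mts2_years * per_year),
        lethal=_shift(surgery_date, timeline.survival_years * per_year),
    )


def growth_curve(
    d_surgery_mm: float,
    params: StageParameters,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    step_days: float = 30.0,
) -> list[tuple[float, float | None, float | None]]:
    """Sample both growth curves on the shared clock.

    Returns ``(offset_days, pt_diameter_mm, mts_diameter_mm)`` tuples from
    the first PT cell (offset 0) to the lethal endpoint.  The PT curve is
    ``None`` after surgery (resection); the MTS curve is ``None`` before
    seeding.  The lethal endpoint is always included as the final sample.
    """
    if step_days <= 0:
        raise GrowthDomainError("step_days must be strictly positive")
    c = constants
    t = compute_timeline(d_surgery_mm, params, c)
    per_year = c.days_per_year
    surgery_day = t.total_pt_years * per_year
    seed_day = surgery_day - t.nonvisible_mts1_years * per_year
    end_day = surgery_day + t.survival_years * per_year
    tvdt = params.tvdt_days
    tau_mts = tvdt / params.k_smts

    samples: list[tuple[float, float | None, float | None]] = []
    offsets = [step_days * i for i in range(int(end_day / step_days) + 1)]
    if offsets[-1] < end_day:
        offsets.append(end_day)
    for day in offsets:
        pt = (
            diameter_from_doublings(day / tvdt, c)
            if day <= surgery_day
            else None
        )
        mts = (
            diameter_from_doublings((day - seed_day) / tau_mts, c)
            if day >= seed_day
            else None
        )
        samples.append((day, pt, mts))
    return samples
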