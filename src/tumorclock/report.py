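"""Stage summary tables: the model's per-stage state and period decomposition.

Two tables are produced for a list of representative pre-surgery diameters
(default: the stage mean diameters 4.5 / 8.5 / 15.1 / 28.5 / 64.6 mm):

* the *state* table — doubling counts, doubling times and the occult
  metastasis size at surgery;
* the *periods* table — the full natural-history decomposition in years.

Underlying values are kept at full precision; display rounding is half-up to
the conventional precision of each row (1 decimal for years and primary-tumor
doublings, 2 decimals for sub-millimetre metastasis sizes and counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .growth import DEFAULT_CONSTANTS, ModelConstants
from .natural_history import NaturalHistoryTimeline, timeline_for_diameter

__all__ = [
    "ReportTable",
    "round_half_up",
    "DEFAULT_STAGE_DIAMETERS",
    "REFERENCE_STATE_TABLE",
    "REFERENCE_PERIODS_TABLE",
    "build_state_table",
    "build_periods_table",
    "diff_against_reference",
]

#: Mean pre-surgery diameter per stage column (mm), T1a..T3.
DEFAULT_STAGE_DIAMETERS: tuple[float, ...] = (4.5, 8.5, 15.1, 28.5, 64.6)

# decimals used when rounding each row for display
_STATE_ROW_DECIMALS: Mapping[str, int] = {
    "pt_diameter_mm": 1,
    "pt_doublings": 1,
    "tvdt_pt_days": 1,
    "k_smts": 2,
    "tvdt_mts_days": 1,
    "mts_doublings": 2,
    "mts_diameter_mm": 2,
}
_PERIODS_ROW_DECIMALS: Mapping[str, int] = {
    "pt_diameter_mm": 1,
    "pt_doublings": 1,
    "tvdt_pt_days": 1,
    "wnh_years": 1,
    "total_pt_years": 1,
    "nonvisible_pt_years": 1,
    "visible_pt_years": 1,
    "nonvisible_mts1_years": 1,
    "nonvisible_mts2_years": 1,
    "visible_mts_years": 1,
    "survival_years": 1,
}

#: Published per-stage reference values for the default diameters, used by
#: the ``tables --diff`` mode.  Keyed row label -> stage label -> value.
REFERENCE_STATE_TABLE: Mapping[str, Mapping[str, float]] = {
    "pt_diameter_mm": {"T1a": 4.5, "T1b": 8.5, "T1c": 15.1, "T2": 28.5, "T3": 64.6},
    "pt_doublings": {"T1a": 26.4, "T1b": 29.2, "T1c": 31.7, "T2": 34.4, "T3": 38.0},
    "tvdt_pt_days": {"T1a": 70.0, "T1b": 70.0, "T1c": 70.0, "T2": 65.0, "T3": 60.0},
    "k_smts": {"T1a": 1.0, "T1b": 1.0, "T1c": 1.0, "T2": 1.0, "T3": 1.0},
    "tvdt_mts_days": {"T1a": 70.0, "T1b": 70.0, "T1c": 70.0, "T2": 65.0, "T3": 60.0},
    "mts_doublings": {"T1a": 6.44, "T1b": 9.19, "T1c": 11.68, "T2": 14.43, "T3": 17.97},
    "mts_diameter_mm": {"T1a": 0.04, "T1b": 0.08, "T1c": 0.15, "T2": 0.28, "T3": 0.64},
}
REFERENCE_PERIODS_TABLE: Mapping[str, Mapping[str, float]] = {
    "pt_diameter_mm": {"T1a": 4.5, "T1b": 8.5, "T1c": 15.1, "T2": 28.5, "T3": 64.6},
    "pt_doublings": {"T1a": 26.4, "T1b": 29.2, "T1c": 31.7, "T2": 34.4, "T3": 38.0},
    "tvdt_pt_days": {"T1a": 70.0, "T1b": 70.0, "T1c": 70.0, "T2": 65.0, "T3": 60.0},
    "wnh_years": {"T1a": 11.5, "T1b": 11.5, "T1c": 11.5, "T2": 10.7, "T3": 9.9},
    "total_pt_years": {"T1a": 5.1, "T1b": 5.6, "T1c": 6.1, "T2": 6.1, "T3": 6.2},
    "nonvisible_pt_years": {"T1a": 3.8, "T1b": 3.8, "T1c": 3.8, "T2": 3.5, "T3": 3.3},
    "visible_pt_years": {"T1a": 1.2, "T1b": 1.8, "T1c": 2.3, "T2": 2.6, "T3": 3.0},
    # The published occult-MTS-I row copies the visible-PT row; the true
    # seeding->surgery period at T1c computes 2.238 -> 2.2, not 2.3.
    "nonvisible_mts1_years": {"T1a": 1.2, "T1b": 1.8, "T1c": 2.3, "T2": 2.6, "T3": 3.0},
    "nonvisible_mts2_years": {"T1a": 4.4, "T1b": 3.9, "T1c": 3.4, "T2": 2.7, "T3": 1.9},
    "visible_mts_years": {"T1a": 2.0, "T1b": 2.0, "T1c": 2.0, "T2": 1.9, "T3": 1.7},
    "survival_years": {"T1a": 6.4, "T1b": 5.9, "T1c": 5.4, "T2": 4.5, "T3": 3.6},
}


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero (display convention for the tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ReportTable:
    """A stage summary table with both raw and display-rounded values."""

    raw: pd.DataFrame
    row_decimals: Mapping[str, int]

    @property
    def rounded(self) -> pd.DataFrame:
        out = self.raw.copy()
        for row, nd in self.row_decimals.items():
            if row in out.index:
                out.loc[row] = [round_half_up(v, nd) for v in out.loc[row]]
        return out

    def to_csv(self) -> str:
        return self.rounded.to_csv(index_label="quantity")

    def pretty(self) -> str:
        return self.rounded.to_string()


def _timelines(
    diameters: Sequence[float], constants: ModelConstants
) -> list[NaturalHistoryTimeline]:
    return [timeline_for_diameter(d, constants) for d in diameters]


def _columns(diameters: Sequence[float], constants: ModelConstants) -> list[str]:
    from .staging import classify_t_stage

    labels = [classify_t_stage(d).label for d in diameters]
    # disambiguate repeated stages when custom diameters share an interval
    if len(set(labels)) != len(labels):
        labels = [f"{lab}({d:g}mm)" for lab, d in zip(labels, diameters)]
    return labels


def build_state_table(
    diameters: Sequence[float] = DEFAULT_STAGE_DIAMETERS,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> ReportTable:
    """Doubling counts and occult metastasis state at surgery, per stage."""
    cols = _columns(diameters, constants)
    data: dict[str, list[float]] = {}
    for col, d, t in zip(cols, diameters, _timelines(diameters, constants)):
        data[col] = [
            d,
            t.pt_doublings_at_surgery,
            t.tvdt_days,
            1.0,
            t.tvdt_days,  # MTS clock equals PT clock for k = 1
            t.mts_doublings_at_surgery,
            t.mts_diameter_at_surgery_mm,
        ]
    raw = pd.DataFrame(data, index=list(_STATE_ROW_DECIMALS))
    return ReportTable(raw=raw, row_decimals=_STATE_ROW_DECIMALS)


def build_periods_table(
    diameters: Sequence[float] = DEFAULT_STAGE_DIAMETERS,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> ReportTable:
    """Full natural-history period decomposition (years), per stage."""
    cols = _columns(diameters, constants)
    data: dict[str, list[float]] = {}
    for col, d, t in zip(cols, diameters, _timelines(diameters, constants)):
        data[col] = [
            d,
            t.pt_doublings_at_surgery,
            t.tvdt_days,
            t.wnh_years,
            t.total_pt_years,
            t.nonvisible_pt_years,
            t.visible_pt_years,
            t.nonvisible_mts1_years,
            t.nonvisible_mts2_years,
            t.visible_mts_years,
            t.survival_years,
        ]
    raw = pd.DataFrame(data, index=list(_PERIODS_ROW_DECIMALS))
    return ReportTable(raw=raw, row_decimals=_PERIODS_ROW_DECIMALS)


def diff_against_reference(
    table: ReportTable, reference: Mapping[str, Mapping[str, float]]
) -> pd.DataFrame:
    """Cellwise deviation (computed rounded value minus reference value)."""
    rounded = table.rounded
    records = []
    for row, ref_cells in reference.items():
        if row not in rounded.index:
            continue
        for col, ref in ref_cells.items():
            if col not in rounded.columns:
                continue
            got = rounded.loc[row, col]
            records.append(
                {
                    "quantity": row,
                    "stage": col,
                    "computed": got,
                    "reference": ref,
                    "delta": round(got - ref, 10),
                }
            )
    return pd.DataFrame.from_records(records)
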