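"""Size-based T staging and the per-stage growth parameters.

The T category is determined by the pre-surgery primary-tumor diameter on
half-open intervals (lo, hi]::

    T1a (1, 5]   T1b (5, 10]   T1c (10, 20]   T2 (20, 50]   T3 (50, inf)

T4 is defined clinically (chest-wall/skin involvement), not by size, and is
never returned by the classifier; it can still be passed explicitly to
obtain its growth parameters.

Each stage carries a mean tumor volume doubling time (days) and a
multiplicative coefficient ``k_smts`` relating the metastasis growth rate to
the primary's (1.00 for node-negative disease).  Only N0 is supported; the
model does not describe node-positive disease.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .errors import ConfigError, UnstageableError, UnsupportedNodalStatusError

__all__ = [
    "TStage",
    "StageParameters",
    "STAGE_TABLE_VERSION",
    "T_STAGES",
    "T4_STAGE",
    "classify_t_stage",
    "stage_parameters",
    "get_stage",
    "load_stage_table",
]

#: Default TVDT for T4: the model text gives only a 46-48 day range; the
#: midpoint is used and can be overridden via ``stage_parameters(t4_tvdt_days=...)``.
T4_TVDT_DAYS = 47.0

STAGE_TABLE_VERSION = 1


@dataclass(frozen=True)
class TStage:
    """A T category with its defining diameter interval (lo, hi] in mm.

    ``lo`` is exclusive and ``hi`` inclusive; ``hi = inf`` means unbounded.
    ``lo = hi = nan`` flags a stage not determined by size (T4).
    """

    label: str
    lo_mm: float
    hi_mm: float

    @property
    def size_determined(self) -> bool:
        return not math.isnan(self.lo_mm)

    def contains(self, d_mm: float) -> bool:
        if not self.size_determined:
            return False
        return self.lo_mm < d_mm <= self.hi_mm

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class StageParameters:
    """Growth parameters attached to a stage: TVDT (days) and MTS-rate coefficient."""

    tvdt_days: float
    k_smts: float = 1.0

    def __post_init__(self) -> None:
        if self.tvdt_days <= 0:
            raise ConfigError("tvdt_days must be strictly positive")
        if self.k_smts <= 0:
            raise ConfigError("k_smts must be strictly positive")


# stage label -> (lo, hi, tvdt_days, k_smts); order matters for the scan
_DEFAULT_ROWS: Sequence[tuple[str, float, float, float, float]] = (
    ("T1a", 1.0, 5.0, 70.0, 1.0),
    ("T1b", 5.0, 10.0, 70.0, 1.0),
    ("T1c", 10.0, 20.0, 70.0, 1.0),
    ("T2", 20.0, 50.0, 65.0, 1.0),
    ("T3", 50.0, math.inf, 60.0, 1.0),
)

T_STAGES: tuple[TStage, ...] = tuple(
    TStage(label, lo, hi) for label, lo, hi, _, _ in _DEFAULT_ROWS
)
T4_STAGE = TStage("T4", math.nan, math.nan)

_DEFAULT_PARAMS: Mapping[str, StageParameters] = {
    label: StageParameters(tvdt, k) for label, _, _, tvdt, k in _DEFAULT_ROWS
} | {"T4": StageParameters(T4_TVDT_DAYS, 1.0)}


def get_stage(label: str) -> TStage:
    """Look up a stage by label (``T1a`` ... ``T4``)."""
    for stage in T_STAGES:
        if stage.label == label:
            return stage
    if label == "T4":
        return T4_STAGE
    raise ConfigError(f"unknown T stage label: {label!r}")


def classify_t_stage(
    d_mm: float, stages: Sequence[TStage] = T_STAGES
) -> TStage:
    """Assign the size-based T category for a pre-surgery diameter.

    Raises :class:`UnstageableError` below 1 mm (sub-visible lesions carry no
    size category).  T4 is never returned.
    """
    for stage in stages:
        if stage.contains(d_mm):
            return stage
    raise UnstageableError(
        f"diameter {d_mm} mm is at or below the 1 mm staging floor; "
        "no size-based T category applies"
    )


def stage_parameters(
    stage: TStage | str,
    nodal_status: str = "N0",
    *,
    t4_tvdt_days: float = T4_TVDT_DAYS,
    table: Mapping[str, StageParameters] | None = None,
) -> StageParameters:
    """Growth parameters (TVDT, k_smts) for a stage and nodal status.

    Only ``N0`` is supported: the model is restricted to node-negative
    disease and raises for any other nodal status.
    """
    if nodal_status != "N0":
        raise UnsupportedNodalStatusError(
            f"nodal status {nodal_status!r} is outside the model's scope; "
            "only node-negative (N0) disease is described"
        )
    label = stage.label if isinstance(stage, TStage) else stage
    params = dict(_DEFAULT_PARAMS if table is None else table)
    if label == "T4" and table is None:
        params["T4"] = StageParameters(t4_tvdt_days, 1.0)
    if label not in params:
        raise ConfigError(f"unknown T stage label: {label!r}")
    return params[label]


def load_stage_table(
    path: str | Path,
) -> tuple[tuple[TStage, ...], Mapping[str, StageParameters]]:
    """Load an alternate stage table from a JSON config file.

    Expected schema::

        {"version": 1,
         "stages": [{"label": "T1a", "lo_mm": 1, "hi_mm": 5,
                     "tvdt_days": 70.0, "k_smts": 1.0}, ...]}

    ``hi_mm: null`` means unbounded.  Intervals must be disjoint and ordered.
    """
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(
            f"stage table {path}: invalid JSON at line {exc.lineno}: {exc.msg}"
        ) from exc
    if raw.get("version") != STAGE_TABLE_VERSION:
        raise ConfigError(
            f"stage table {path}: unsupported version {raw.get('version')!r}"
        )
    stages: list[TStage] = []
    params: dict[str, StageParameters] = {}
    prev_hi = None
    for row in raw.get("stages", []):
        try:
            label = row["label"]
            lo = float(row["lo_mm"])
            hi = math.inf if row["hi_mm"] is None else float(row["hi_mm"])
            params[label] = StageParameters(
                float(row["tvdt_days"]), float(row.get("k_smts", 1.0))
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"stage table {path}: bad row {row!r}") from exc
        if prev_hi is not None and lo != prev_hi:
            raise ConfigError(
                f"stage table {path}: intervals must tile without gaps "
                f"(stage {label} starts at {lo}, previous ended at {prev_hi})"
            )
        prev_hi = hi
        stages.append(TStage(label, lo, hi))
    if not stages:
        raise ConfigError(f"stage table {path}: no stages defined")
    return tuple(stages), params
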