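"""Exception hierarchy for tumorclock.

All domain errors derive from :class:`TumorClockError` so callers (and the
CLI) can distinguish model-domain failures from programming errors.
"""


class TumorClockError(ValueError):
    """Base class for all model-domain errors."""


class GrowthDomainError(TumorClockError):
    """Input outside the valid domain of a growth conversion."""


class NonGrowthError(TumorClockError):
    """Serial measurements show no growth; the doubling-time estimator is undefined."""


class ChronologyError(TumorClockError):
    """Measurement dates are not in increasing order."""


class UnstageableError(TumorClockError):
    """Diameter too small to assign a size-based T category."""


class UnsupportedNodalStatusError(TumorClockError):
    """Nodal status outside the model's scope (only N0 is described)."""


class PastLethalError(TumorClockError):
    """Requested state lies beyond the lethal end of the doubling clock."""


class ConfigError(TumorClockError):
    """Invalid simulation or stage-table configuration."""
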