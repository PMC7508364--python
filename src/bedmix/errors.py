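"""Exception and warning hierarchy for bedmix."""


class BedmixError(Exception):
    """Base class for all bedmix errors."""


class SchemaError(BedmixError):
    """Input table is malformed: missing column, empty file, wrong header."""


class RowParseError(BedmixError):
    """A data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class UniquenessError(BedmixError):
    """Duplicate (region, ward, year) key within a table."""


class InvariantViolationError(BedmixError):
    """A record violates a data-model invariant (e.g. days < discharges)."""


class MixedYearsError(BedmixError):
    """Aggregation would pool distinct calendar years without being asked to."""


class UndefinedIndicatorError(BedmixError):
    """Indicator denominator is zero (no discharges, no beds, no population)."""


class BenchmarkError(BedmixError):
    """Benchmark construction or region/benchmark matching failed."""


class RecoveryToleranceError(BedmixError):
    """A parameter-recovery experiment exceeded its stated tolerance."""


class UnknownWardWarning(UserWarning):
    """Ward code outside the controlled vocabulary (list may extend)."""


class IndicatorOverflowWarning(UserWarning):
    """Occupancy above endowment: BOR > 100% or negative turnover interval."""
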