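"""Exception hierarchy for dietshift."""


class DietShiftError(Exception):
    """Base class for all package errors."""


class SchemaError(DietShiftError):
    """An input table is missing a required column or has an unusable layout."""


class ValidationFailed(DietShiftError):
    """A parsed database violates one or more structural invariants."""

    def __init__(self, issues):
        self.issues = list(issues)
        lines = "; ".join(f"{i.item_id}:{i.rule}" for i in self.issues[:10])
        more = "" if len(self.issues) <= 10 else f" (+{len(self.issues) - 10} more)"
        super().__init__(f"database validation failed: {lines}{more}")


class CoverageError(DietShiftError):
    """A required item, group, nutrient or indicator is absent from the data."""


class DataError(DietShiftError):
    """A value is outside its admissible domain (e.g. waste fraction >= 1)."""


class InfeasibleSubstitution(DietShiftError):
    """All replacement targets are capped before the removed amount is placed.

    ``residual`` holds the unallocated quantity in the functional unit of the
    scenario (grams on a mass basis, kcal on an energy basis).
    """

    def __init__(self, residual: float, unit: str):
        self.residual = residual
        self.unit = unit
        super().__init__(f"substitution infeasible: {residual:.6g} {unit} unallocated")


class PipelineUsageError(DietShiftError):
    """The caller combined pipeline pieces inconsistently (e.g. no BAU)."""
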