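"""Exception hierarchy shared across the package."""


class DistcostError(Exception):
    """Base class for all errors raised by distcost."""


class GeometryError(DistcostError):
    """Invalid or empty geometry for a spatial unit."""


class DegenerateInputError(DistcostError):
    """Input that is structurally valid but carries no information
    (e.g. all populations zero, fewer pairs than the statistic needs)."""


class ValidationError(DistcostError):
    """A value outside its documented domain (prevalence not in [0, 1],
    gender not in {0, 1}, ...)."""


class SchemaError(DistcostError):
    """An input file that does not match the documented schema.

    Carries ``rows``: a list of (row_number, message) tuples for
    row-level problems, 1-based counting the header as row 1.
    """

    def __init__(self, message: str, rows: list | None = None):
        super().__init__(message)
        self.rows = rows or []


class UnreachableError(DistcostError):
    """Origin-destination pairs with no path on the road network.

    Carries ``unit_ids``: the origins that could not reach the facility.
    """

    def __init__(self, message: str, unit_ids: list | None = None):
        super().__init__(message)
        self.unit_ids = unit_ids or []
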