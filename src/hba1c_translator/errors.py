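"""Exception hierarchy.

Hard bounds (type invariants) raise; literature-range violations only warn.
"""


class ModelError(Exception):
    """Base class for all domain errors raised by this package."""


class ParameterError(ModelError):
    """A parameter file or value violates a hard invariant."""


class MissingComplicationError(ParameterError):
    """A required complication is absent from a parameter or cost set."""

    def __init__(self, complication_id: str, context: str = "parameter set"):
        self.complication_id = complication_id
        super().__init__(f"complication '{complication_id}' missing from {context}")


class UnknownCountryError(ModelError):
    def __init__(self, country: str, available: list[str]):
        self.country = country
        self.available = sorted(available)
        super().__init__(
            f"no cost data set for country '{country}'; available: {', '.join(self.available)}"
        )


class AmbiguousCostSetError(ModelError):
    """Several cost data sets exist for the country; an explicit source is required."""

    def __init__(self, country: str, source_ids: list[str]):
        self.country = country
        self.source_ids = sorted(source_ids)
        super().__init__(
            f"{len(self.source_ids)} cost data sets for '{country}'; "
            f"pass source_id, one of: {', '.join(self.source_ids)}"
        )


class ProjectionError(ModelError):
    """The projection left the model's validity domain (e.g. incidence > 1)."""
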