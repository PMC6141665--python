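"""Exception hierarchy.

All glycopap errors derive from :class:`GlycopapError` so callers can catch
the whole family; each subclass maps to one failure mode of the pipeline
contracts (schema, value validation, geometry, configuration).
"""


class GlycopapError(Exception):
    """Base class for all glycopap errors."""


class SchemaError(GlycopapError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(GlycopapError):
    """A value violates a domain invariant (e.g. non-positive diameter)."""


class GeometryError(GlycopapError):
    """A geometric computation received degenerate input (empty mesh, zero-length perimeter)."""


class ConfigurationError(GlycopapError):
    """A configuration value is outside its admissible range (e.g. |rho| >= 1)."""
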