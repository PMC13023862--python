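"""Exception hierarchy for the dpiat package.

All data-facing errors derive from :class:`ValueError` so that callers who do
not care about the fine-grained class can catch one thing.
"""


class DpiatError(ValueError):
    """Base class for all package-specific errors."""


class ParameterError(DpiatError):
    """An invalid simulation or configuration parameter."""


class ValidationError(DpiatError):
    """Data violated a documented invariant (block range, latency ordering...)."""


class SchemaError(ValidationError):
    """A tabular file is missing required columns or has a malformed header."""


class DegenerateDataError(DpiatError):
    """Data technically valid but unusable (zero pooled SD, constant sample)."""


class StructureError(DpiatError):
    """A session is missing a block required by the scoring algorithm."""


class ConfigurationError(DpiatError):
    """A pipeline run is missing a required input (norms, cases, trials)."""


class NumericError(RuntimeError):
    """A numerical routine failed to converge; carries diagnostics in args."""
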