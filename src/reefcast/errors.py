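"""Exception hierarchy shared by all reefcast modules."""


class ReefcastError(Exception):
    """Base class for errors raised by reefcast."""


class InvalidParameterError(ReefcastError, ValueError):
    """A function argument is out of its physically meaningful range."""


class ConfigurationError(ReefcastError, ValueError):
    """A rate table, response curve, or experiment config is incomplete
    or inconsistent (e.g. a census taxon with no rate and no fallback)."""


class CoverageError(ReefcastError, ValueError):
    """A time series does not cover the years an operation needs."""
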