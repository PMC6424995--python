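"""Exception hierarchy shared across the package."""


class BsaHopperError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(BsaHopperError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class DataError(BsaHopperError, ValueError):
    """Malformed or inconsistent input data."""


class NonCodingError(DataError):
    """A genomic position does not fall inside any CDS segment of a gene."""


class NoVariationError(DataError):
    """An association test was requested on a single genotype class."""
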