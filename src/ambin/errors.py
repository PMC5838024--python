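"""Exception hierarchy shared across the package."""


class AmbinError(Exception):
    """Base class for all package-specific errors."""


class ArgumentError(AmbinError, ValueError):
    """An argument violated a documented precondition."""


class ParseError(AmbinError, ValueError):
    """A text input could not be parsed; message names the offending line."""


class LookupTaxonError(AmbinError, KeyError):
    """A taxon or accession was not found in the reference structures."""


class DepthError(AmbinError, ValueError):
    """A sample is shallower than the requested rarefaction depth."""


class ConsistencyError(AmbinError, ValueError):
    """An internal bookkeeping invariant was violated (e.g. a read assigned twice)."""


class SaturationError(AmbinError, ValueError):
    """A pairwise divergence is at or beyond the Jukes-Cantor saturation bound."""


class ConfigError(AmbinError, ValueError):
    """A run configuration failed validation before any stage executed."""
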