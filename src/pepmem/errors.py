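"""Exception hierarchy shared across pepmem."""


class PepmemError(Exception):
    """Base class for all pepmem errors."""


class InvalidInputError(PepmemError, ValueError):
    """Input data violates a precondition (wrong shape, empty, out of range)."""


class LogDomainError(InvalidInputError):
    """A logarithm was requested of a non-positive quenching ratio."""


class FitDegenerateError(PepmemError, ValueError):
    """The data admit no valid fit (e.g. no interior maximum in a depth profile)."""


class SelectionError(PepmemError, ValueError):
    """An atom/residue selection resolved to nothing or to missing atoms."""


class DegenerateGeometryError(PepmemError, ValueError):
    """A geometric quantity is undefined (zero-length vector, parallel projection)."""


class ClashError(PepmemError, ValueError):
    """Two atoms are unphysically close for the requested computation."""


class ConfigError(PepmemError, ValueError):
    """A run configuration is malformed or references missing files."""
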