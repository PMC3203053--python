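"""Exception hierarchy for transportscope.

Every error raised by the package derives from :class:`TransportScopeError`
so callers can catch the package's failures with a single ``except``.
"""


class TransportScopeError(Exception):
    """Base class for all transportscope errors."""


class ParseError(TransportScopeError):
    """A structure or trajectory file could not be parsed."""


class EmptyInputError(TransportScopeError):
    """An operation received zero atoms, frames, or points."""


class SelectionError(TransportScopeError):
    """A selection expression resolved to nothing or referenced absent atoms."""


class TopologyMismatchError(TransportScopeError):
    """Atom counts of a trajectory/reference do not match the topology."""


class DegenerateGeometryError(TransportScopeError):
    """Geometry is degenerate (too few points, collinear, zero-length axis)."""


class InsufficientFramesError(TransportScopeError):
    """An operation needs more frames than the trajectory provides."""


class InsufficientDataError(TransportScopeError):
    """A fit needs more distinct data points than were supplied."""


class MissingAtomError(TransportScopeError):
    """A residue lacks an atom required by the requested measurement."""


class ConfigurationError(TransportScopeError):
    """An analysis configuration is internally inconsistent."""


class UnitError(TransportScopeError):
    """Two quantities with incompatible units were combined."""


class NoOverlapError(TransportScopeError):
    """Profiles or series to be compared share no common domain."""
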