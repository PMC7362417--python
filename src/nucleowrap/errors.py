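"""Exception hierarchy.

Every error raised on a user-facing code path derives from
:class:`NucleowrapError`, so callers can catch one base class at pipeline
boundaries while tests assert on the specific subclass.
"""


class NucleowrapError(Exception):
    """Base class for all package errors."""


class FormatError(NucleowrapError):
    """A file could not be parsed in the declared format."""


class PairingError(NucleowrapError):
    """DNA strands could not be paired into an ordered base-pair list."""


class ConfigurationError(NucleowrapError):
    """A chain role, copy pairing or run configuration is missing/invalid."""


class TopologyError(NucleowrapError):
    """Structure/trajectory topology is inconsistent (atom counts, empty sets)."""


class SelectionError(NucleowrapError):
    """An atom selection is empty, mismatched or otherwise unusable."""


class GeometryError(NucleowrapError):
    """Degenerate or infeasible geometry (zero-length rays, colliding arms)."""


class ValidationError(NucleowrapError):
    """A spec object violates its invariants."""


class RangeError(NucleowrapError):
    """A region does not intersect the axis it is applied to."""


class DefinitionError(NucleowrapError):
    """An operation is undefined for its input (e.g. empty native-contact set)."""


class SampleSizeError(NucleowrapError):
    """Too few observations for the requested statistic."""
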