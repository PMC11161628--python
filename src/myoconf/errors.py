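"""Exception hierarchy for myoconf.

Every error raised by the library derives from :class:`MyoconfError` so that
callers (and the CLI) can catch package failures with a single except clause.
"""


class MyoconfError(Exception):
    """Base class for all myoconf errors."""


class FormatError(MyoconfError):
    """A structure or trajectory file could not be parsed."""


class EmptyStructureError(MyoconfError):
    """A parsed file contained zero atoms."""


class TopologyError(MyoconfError):
    """Frame atom count does not match the topology."""


class SelectionError(MyoconfError):
    """A selection expression is invalid or resolves to nothing where
    a non-empty selection is required."""


class PairingError(MyoconfError):
    """No residue correspondence could be established between two structures."""


class DegenerateGeometryError(MyoconfError):
    """Fewer than three pairs, or collinear points, passed to a superposition."""


class RejectionCollapseError(MyoconfError):
    """Iterative outlier rejection discarded every atom pair."""


class MonitorError(MyoconfError):
    """A geometric monitor anchor could not be resolved on the topology."""


class SeriesError(MyoconfError):
    """Mismatched collective-variable series."""


class EmptyLandscapeError(MyoconfError):
    """A density grid carries no probability mass."""


class UndefinedBasinError(MyoconfError):
    """A basin region has zero probability mass."""


class ComparabilityError(MyoconfError):
    """Two pocket profiles were computed with different cutoffs."""


class AlignmentError(MyoconfError):
    """The reference sequence is missing from a multiple sequence alignment."""


class ConfigError(MyoconfError):
    """A required configuration entry (coefficient, reference angle...) is missing."""


class InterfaceError(MyoconfError):
    """Too few interface residues resolve on query or reference."""


class SpecError(MyoconfError):
    """A synthetic-generator specification is degenerate or infeasible."""
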