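"""Exception hierarchy for aquagate.

All package-raised errors derive from :class:`AquagateError` so callers can
catch pipeline failures with a single except clause while still
distinguishing I/O, geometry and statistics failures by subclass.
"""


class AquagateError(Exception):
    """Base class for all aquagate errors."""


class ParseError(AquagateError):
    """A structure or trajectory file could not be parsed."""


class StructuralError(AquagateError):
    """Frames/topology disagree (atom counts, missing atoms)."""


class OrderingError(AquagateError):
    """Trajectory times are not strictly increasing."""


class SelectionError(AquagateError):
    """An atom/residue selection could not be resolved."""


class UnderdeterminedFitError(SelectionError):
    """Fewer than three atoms were selected for a rigid-body fit."""


class ConfigurationError(AquagateError):
    """Invalid user-supplied parameters (scheme, cylinder, filter, config)."""


class EmptySelectionError(SelectionError):
    """A selection matched no atoms (e.g. no waters in the topology)."""


class UndefinedStatisticError(AquagateError):
    """A statistic was requested on an empty sample."""


class UndefinedTorsionError(AquagateError):
    """Torsion angle undefined because three consecutive atoms are colinear."""


class AssemblyError(AquagateError):
    """Interval dataset assembly failed (missing trace/series)."""


class FitError(AquagateError):
    """Model fitting failed or the data are degenerate."""


class CapabilityError(AquagateError):
    """The input lacks information required by the requested analysis."""
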