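"""Exception hierarchy shared by all analysis stages."""


class VardynError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(VardynError):
    """A coordinate record could not be parsed; the message names the line."""


class StructureError(VardynError):
    """Models of a multi-model file are mutually inconsistent."""


class SelectionError(VardynError):
    """An atom selection cannot be satisfied by the topology."""


class SpecError(VardynError):
    """A synthetic-data specification violates its invariants."""


class InsufficientFramesError(VardynError):
    """An operation needs more trajectory frames than were supplied."""


class DegenerateInputError(VardynError):
    """Geometric input is too degenerate for the requested operation."""


class RadiusTableError(VardynError):
    """An element has no van der Waals radius in the active table."""


class ConfigError(VardynError):
    """A run-time configuration value is invalid or inapplicable."""


class ScoreTableError(VardynError):
    """A variant score table cell or column cannot be interpreted."""


class ComparisonError(VardynError):
    """Two per-residue profiles share no residues."""


class LandscapeError(VardynError):
    """A free-energy landscape has no populated bins."""
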