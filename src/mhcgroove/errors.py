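"""Exception hierarchy.

Every error raised by the library derives from :class:`MhcGrooveError`, so
callers (and the CLI) can distinguish computation failures from usage bugs.
"""


class MhcGrooveError(Exception):
    """Base class for all mhcgroove errors."""


class StructureFormatError(MhcGrooveError):
    """A structure file could not be parsed, or parsed to an empty model."""


class RoleAssignmentError(MhcGrooveError):
    """Chain roles could not be assigned unambiguously."""


class SelectionError(MhcGrooveError):
    """A chain/role selection produced an empty or invalid subset."""


class SasaError(MhcGrooveError):
    """Invalid input to the accessible-surface-area computation."""


class GeometryError(MhcGrooveError):
    """Degenerate or insufficient geometry (frames, axes, superposition)."""


class ScreenError(MhcGrooveError):
    """Invalid input to the peptide off-target screen."""


class FixtureError(MhcGrooveError):
    """A synthetic fixture specification is infeasible."""
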