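"""Exception hierarchy for mdcontacts.

Every error raised by the package derives from :class:`MDContactsError`,
so callers (and the CLI) can catch one type at pipeline boundaries.
"""


class MDContactsError(Exception):
    """Base class for all mdcontacts errors."""


class StructureIOError(MDContactsError):
    """Unreadable or malformed structure file."""


class EmptyStructureError(StructureIOError):
    """A PDB file contained zero usable ATOM records."""


class ElementError(StructureIOError):
    """An atom's element could not be resolved against the mass table."""


class TopologyError(MDContactsError):
    """Trajectory frames disagree on (chain, residue, atom) topology."""


class ChainCountError(MDContactsError):
    """An interface operation requires exactly two chains."""


class EmptyInputError(MDContactsError):
    """An operation received an empty collection where >= 1 item is required."""


class MassError(MDContactsError):
    """A residue has zero total mass (no atoms with resolvable mass)."""


class ResidueNotFoundError(MDContactsError, KeyError):
    """A residue identity was not found in the structure."""


class ParameterError(MDContactsError, ValueError):
    """A generator or criteria parameter violates its invariants."""


class CapacityError(ParameterError):
    """A planted feature count exceeds what the fixture geometry can hold."""


class PipelineError(MDContactsError):
    """A pipeline stage failed; message carries stage name and file."""
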