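"""Exception hierarchy for greensolv.

Everything derives from :class:`GreensolvError` so callers can catch the
package's failures with one handler; the concrete subclasses mirror the
distinct failure modes of the screening pipeline.
"""


class GreensolvError(Exception):
    """Base class for all greensolv errors."""


class InvalidInputError(GreensolvError, ValueError):
    """A scalar or array argument violates a precondition (non-finite, negative...)."""


class InvalidSphereError(InvalidInputError):
    """A solubility sphere has a non-positive radius."""


class EmptyInputError(InvalidInputError):
    """An operation received an empty collection where at least one item is required."""


class DuplicateIdentifierError(InvalidInputError):
    """Solvent or solute names repeat within a set that requires uniqueness."""


class UnknownIdentifierError(GreensolvError, KeyError):
    """A referenced solvent/solute/analyte name is not present in the input."""


class UnderdeterminedError(InvalidInputError):
    """Too few observations to constrain the four sphere parameters."""


class RankDeficientError(InvalidInputError):
    """Degenerate solvent geometry (coincident Hansen coordinates)."""


class NormalizationError(InvalidInputError):
    """A relative-solubility row is not normalized (row maximum differs from 0)."""


class UndefinedRatioError(InvalidInputError):
    """PUFA/SFA requested for a profile with zero saturated fat."""


class FattyAcidCodeError(InvalidInputError):
    """A fatty-acid code does not match the C<carbons>:<double bonds> pattern."""


class InsufficientOverlapError(InvalidInputError):
    """Fewer than three solvents shared across the tables being joined."""


class InvalidSpecError(InvalidInputError):
    """A synthetic-data specification is internally inconsistent."""
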