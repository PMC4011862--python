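"""Exception hierarchy.

All package errors derive from :class:`RnaCleaveError` so callers (and the
CLI) can catch one base class.  Parsing problems are split into format,
consistency and alphabet errors because they call for different user fixes:
a malformed file, an internally contradictory structure, or a sequence that
is not RNA.
"""


class RnaCleaveError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RnaCleaveError):
    """Input text does not conform to the expected file format."""


class ConsistencyError(FormatError):
    """A structure file is self-contradictory (e.g. asymmetric pairing)."""


class AlphabetError(FormatError):
    """A sequence contains characters outside the RNA alphabet."""


class UnsupportedNotationError(FormatError):
    """Dot-bracket input uses bracket types this package does not model
    (pseudoknot alphabets such as '[', '{' or letters)."""


class UnsupportedStructureError(RnaCleaveError):
    """A structure cannot be expressed in the requested output notation
    (crossing pairs cannot be written as plain dot-bracket)."""


class EnzymeLookupError(RnaCleaveError):
    """Requested enzyme name is not in the built-in registry."""


class ValidationError(RnaCleaveError):
    """Invalid user-supplied parameter (empty residue set, duplicate
    enzyme name, empty panel, ...)."""


class CompatibilityError(ValidationError):
    """A digestion product is not a substring of the reference sequence."""


class ReferenceLengthError(ValidationError):
    """Reference sequence exceeds the maximum length accepted by
    constraint inference (default 200 nt)."""
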