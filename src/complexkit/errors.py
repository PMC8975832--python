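"""Exception hierarchy.

All complexkit errors derive from :class:`ComplexKitError` so callers can
catch one base class; each subclass also derives from the closest builtin
(``ValueError``) for ergonomic use in scripts.
"""


class ComplexKitError(Exception):
    """Base class for all complexkit errors."""


class FormatError(ComplexKitError, ValueError):
    """A file could not be parsed as the expected format."""


class ConsistencyError(ComplexKitError, ValueError):
    """Two inputs that must agree (e.g. PAE matrix vs. model residues) do not."""


class ParameterError(ComplexKitError, ValueError):
    """A parameter is outside its allowed domain."""
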