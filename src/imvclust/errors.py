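"""Exception taxonomy shared across the package.

The CLI maps these onto exit codes: anything derived from
:class:`ImvcError` exits with status 1; click's own usage errors exit 2.
"""


class ImvcError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ImvcError):
    """Input data violates an invariant (bad mask row, NaN features, ...)."""


class StructuralError(ImvcError):
    """Shapes or file layout do not line up (row-count mismatch, ...)."""


class ParameterError(ImvcError):
    """A configuration value is outside its admissible range."""


class DegenerateInputError(ImvcError):
    """The input is valid but the operation is undefined on it
    (e.g. all features maximally entropic, single-row membership)."""


class DivergenceError(ImvcError):
    """Training produced a non-finite loss; the message names the term."""
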