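"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration problems exit 2, data
problems exit 3, degenerate analyses (empty masks, single-class folds,
zero-variance series) exit 4.
"""


class PhytoAffectError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PhytoAffectError):
    """Invalid or inconsistent configuration values."""

    exit_code = 2


class DataError(PhytoAffectError):
    """Malformed, misaligned or otherwise unusable input data."""

    exit_code = 3


class DegenerateAnalysisError(PhytoAffectError):
    """The analysis is structurally impossible on this input.

    Raised for zero-variance series, empty analysis sets after masking,
    single-class training folds, and collinear regression designs.
    """

    exit_code = 4
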