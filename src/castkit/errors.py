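"""Exception hierarchy.

All package-raised errors derive from :class:`CastKitError` so callers can
catch one base class at pipeline boundaries.
"""


class CastKitError(Exception):
    """Base class for all castkit errors."""


class FormatError(CastKitError):
    """A delimited input file is malformed (missing column, bad cell)."""


class PairingError(CastKitError):
    """A mutant-assay well has no matching reference-assay well (or vice versa)."""


class QCError(CastKitError):
    """A plate cannot be quality-controlled (e.g. no NTC wells present)."""


class WorkflowError(CastKitError):
    """The repeat/confirmation workflow was invoked with inconsistent state."""


class CalibrationError(CastKitError):
    """Threshold derivation was attempted without usable calibration data."""


class ParameterError(CastKitError, ValueError):
    """A numeric argument is outside its documented domain."""


class DesignError(CastKitError):
    """A reference-standard design is infeasible with the given materials."""


class RegressionError(CastKitError):
    """A regression cannot be fit (too few points, degenerate predictor)."""
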