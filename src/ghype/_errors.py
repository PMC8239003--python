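"""Exception hierarchy.

All user-facing errors derive from :class:`GHypeError`; the CLI maps
:class:`ValidationError` (and subclasses) to exit status 2.
"""


class GHypeError(Exception):
    """Base class for all ghype errors."""


class ValidationError(GHypeError, ValueError):
    """Invalid input data or inconsistent model/graph combination."""


class FormatError(ValidationError):
    """Malformed input file (bad multiplicity, wrong dialect, ...)."""


class ParameterError(ValidationError):
    """Infeasible generator or model parameters."""


class SaturationError(ValidationError):
    """Propensity estimation hit a saturated dyad (A_ij == Xi_ij)."""


class InfeasibleError(ValidationError):
    """Requested draw count exceeds what the urn can supply."""


class UndefinedOddsError(ValidationError):
    """Odds ratio against a vertex pair with zero stub combinations."""
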