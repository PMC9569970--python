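"""Exception hierarchy for ppptrace.

All package errors derive from :class:`PPPTraceError` so callers can catch
one base class.  Input-validation problems additionally derive from
``ValueError`` to behave naturally in scientific scripts.
"""


class PPPTraceError(Exception):
    """Base class for all ppptrace errors."""


class InvalidInputError(PPPTraceError, ValueError):
    """Malformed or empty input (zero weights, empty lists, bad vectors)."""


class InvalidFragmentError(PPPTraceError, ValueError):
    """Fragment refers to carbon positions outside the analyte backbone."""


class InvalidIntensityError(PPPTraceError, ValueError):
    """Negative ion intensities."""


class DegenerateSampleError(PPPTraceError, ValueError):
    """All-zero intensity vector; no signal to normalize."""


class ConfigurationError(PPPTraceError, ValueError):
    """Missing or inconsistent configuration (e.g. formula absent when required)."""


class ConditioningError(PPPTraceError, ArithmeticError):
    """Correction operator numerically singular."""


class InsufficientReplicatesError(PPPTraceError, ValueError):
    """Bootstrap requires at least two replicate measurements."""


class CalibrationError(PPPTraceError, ValueError):
    """Calibration design rank-deficient or fit invalid."""


class NormalizationError(PPPTraceError, ValueError):
    """Zero/negative baseline or protein amount in a normalization step."""


class IncompleteTraceError(PPPTraceError, ValueError):
    """ECAR trace lacks measurements in one of the four assay phases."""


class UnbalancedDesignError(PPPTraceError, ValueError):
    """Two-way ANOVA requires a balanced (equal replication) design."""


class InvalidGroupingError(PPPTraceError, ValueError):
    """Grouping for a two-sample test has an empty group."""


class SplitImpossibleError(PPPTraceError, ValueError):
    """Median split cannot produce two non-empty groups."""
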