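"""Exception hierarchy.

Every error raised by the analysis pipeline carries a ``stage`` attribute naming
the pipeline stage that failed (``"extract"``, ``"fit"``, ``"segment"``,
``"parameters"`` or ``"input"``), so callers and the CLI can distinguish bad
inputs from analysis failures.
"""


class CeusDroError(Exception):
    """Base class for all package errors."""

    stage: str = "unknown"

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message)
        if stage is not None:
            self.stage = stage


class InputError(CeusDroError, ValueError):
    """Malformed or out-of-contract input (bad file, empty ROI, schema violation)."""

    stage = "input"


class ParameterDomainError(CeusDroError, ValueError):
    """A model parameter outside its mathematical domain (e.g. non-positive mu)."""

    stage = "input"


class NoBolusError(CeusDroError, RuntimeError):
    """The time-intensity curve contains no detectable contrast bolus."""

    stage = "fit"


class AnalysisError(CeusDroError, RuntimeError):
    """A pipeline stage failed on structurally valid input."""

    stage = "analysis"
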