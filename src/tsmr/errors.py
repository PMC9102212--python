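"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: configuration problems exit 2,
data/validation problems exit 3, and a run in which some cohort retains no
usable instrument exits 4.
"""


class TsmrError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(TsmrError):
    """A run configuration or column mapping is unusable."""

    exit_code = 2


class DataValidationError(TsmrError):
    """An input table contains rows that violate a stated invariant."""

    exit_code = 3


class NoUsableInstrumentsError(TsmrError):
    """Harmonization left zero usable instruments for some cohort."""

    exit_code = 4
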