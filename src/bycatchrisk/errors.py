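"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: configuration problems exit 2,
data problems exit 3.
"""


class BycatchRiskError(Exception):
    """Base class for all package errors."""


class ConfigError(BycatchRiskError):
    """Invalid configuration: unknown labels, bad parameters, malformed specs."""


class DataError(BycatchRiskError):
    """Invalid or insufficient input data."""


class AlignmentError(DataError):
    """Tables that must share keys (bin/year) do not."""


class MissingDataError(DataError):
    """A required record (e.g. a cohort year of hatchling production) is absent."""
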