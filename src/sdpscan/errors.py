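"""Exception hierarchy."""


class SdpscanError(Exception):
    """Base class for all package errors."""


class AlignmentFormatError(SdpscanError):
    """Malformed alignment file (ragged rows, unreadable records)."""


class InputError(SdpscanError):
    """Invalid user input (duplicate ids, missing group labels, bad counts)."""


class RateMatrixFormatError(SdpscanError):
    """Malformed PAML-dialect rate-matrix file."""


class ConfigError(SdpscanError):
    """Unknown scorer/model identifier or inconsistent run configuration."""


class EvaluationError(SdpscanError):
    """ROC evaluation cannot proceed (e.g. empty positive set)."""
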