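"""Exception hierarchy shared across the package."""


class ApneaBofError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ApneaBofError):
    """A file could not be parsed as the declared dialect."""


class AlignmentError(ApneaBofError):
    """Signal and annotation streams disagree by more than one minute."""


class InsufficientMetadataError(ApneaBofError):
    """A grouping rule references metadata absent for some records."""

    def __init__(self, rule_name: str, record_ids: list[str]):
        self.rule_name = rule_name
        self.record_ids = list(record_ids)
        super().__init__(
            f"insufficient metadata for rule {rule_name!r}: "
            f"records {', '.join(self.record_ids)}"
        )


class EmptySignalError(ApneaBofError):
    """An operation requiring samples received an empty signal."""


class UnsupportedDurationError(ApneaBofError):
    """Window duration outside the supported {10, 60} s set."""


class BandError(ApneaBofError):
    """A frequency band is invalid for the given signal or scale set."""


class DescriptorError(ApneaBofError):
    """Keypoint/descriptor configuration mismatch."""


class CodebookError(ApneaBofError):
    """Codebook construction failed (e.g. too few descriptors)."""


class LeakageError(ApneaBofError):
    """Train/test contamination detected via provenance tags."""


class TrainingError(ApneaBofError):
    """Classifier training preconditions violated."""


class EvaluationError(ApneaBofError):
    """Cross-validation setup is infeasible for the given data."""
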