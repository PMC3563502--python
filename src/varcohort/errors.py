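"""Exception hierarchy shared across the package."""


class VarcohortError(Exception):
    """Base class for all package errors."""


class HgvsParseError(VarcohortError):
    """A variant string does not conform to the supported c. substitution grammar."""

    def __init__(self, text: str, reason: str):
        self.text = text
        self.reason = reason
        super().__init__(f"cannot parse {text!r}: {reason}")


class InvalidCoordinateError(VarcohortError):
    """A coordinate violates the coding-position contract (e.g. non-positive)."""


class OutOfRangeError(VarcohortError):
    """A coding position falls outside the transcript's CDS."""


class ReferenceMismatchError(VarcohortError):
    """The stated reference allele disagrees with the transcript coding sequence."""

    def __init__(self, variant_key: str, expected: str, observed: str):
        self.variant_key = variant_key
        self.expected = expected
        self.observed = observed
        super().__init__(
            f"{variant_key}: reference allele {observed} does not match "
            f"coding sequence base {expected}"
        )


class ValidationError(VarcohortError):
    """Input records violate a data-model invariant; offending rows are listed."""

    def __init__(self, message: str, records: list | None = None):
        self.records = records or []
        if self.records:
            shown = "; ".join(str(r) for r in self.records[:5])
            message = f"{message} (offending records: {shown}"
            if len(self.records) > 5:
                message += f" … and {len(self.records) - 5} more"
            message += ")"
        super().__init__(message)


class FormatError(VarcohortError):
    """A file is readable but its contents are mostly malformed."""


class ParameterError(VarcohortError):
    """A generator or pipeline parameter is infeasible."""


class PipelineError(VarcohortError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str, records: list | None = None):
        self.stage = stage
        self.records = records or []
        super().__init__(f"[stage: {stage}] {message}")
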