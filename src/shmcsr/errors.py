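"""Exception hierarchy for the shmcsr package."""


class ShmcsrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ShmcsrError):
    """Invalid parameters or configuration.

    ``violations`` lists every problem found, not just the first.
    """

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class RecordRejected(ShmcsrError):
    """A single input record failed a quality rule and is excluded.

    Carries a short machine-readable ``reason`` code so pipeline reports can
    tally rejections without parsing messages.
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        self.detail = detail
        super().__init__(f"{reason}{': ' + detail if detail else ''}")
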