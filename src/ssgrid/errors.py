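"""Exception types shared across the package."""


class SSGError(Exception):
    """Base class for all ssgrid errors."""


class ValidationError(SSGError):
    """Raised when a codebook, trajectory, or input file violates an invariant.

    Carries a list of human-readable violation messages; ``str()`` joins
    them so CLI users see every problem, not just the first.
    """

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class WindowError(SSGError):
    """Raised when a time window does not overlap the observation span."""
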