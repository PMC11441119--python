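"""Exception types raised across the package."""


class ConfigurationError(ValueError):
    """An invalid parameter combination for a randomization procedure or design."""


class DegenerateSequenceError(ValueError):
    """An allocation sequence with an empty arm; the two-sample t-test is undefined."""


class SeriesConvergenceError(RuntimeError):
    """A series evaluation did not reach the requested truncation tolerance."""

    def __init__(self, message: str, achieved_bound: float):
        super().__init__(message)
        self.achieved_bound = achieved_bound
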