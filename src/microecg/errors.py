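"""Exception hierarchy for the µECG analysis pipeline."""


class MicroECGError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MicroECGError, ValueError):
    """An analysis or simulation configuration is internally inconsistent."""


class InputError(MicroECGError, ValueError):
    """A recording, manifest or table is malformed or unreadable."""


class InsufficientBeatsError(MicroECGError, ValueError):
    """An operation needs more detected beats than are available."""


class DegeneratePatternError(MicroECGError, ValueError):
    """An averaged pattern is flat and carries no fiducial information."""


class NoAnalyzableChannelError(MicroECGError, RuntimeError):
    """Beat analysis failed on every channel of a recording.

    Carries a ``diagnostics`` mapping of channel id to the failure reason so
    the caller can report what went wrong per electrode.
    """

    def __init__(self, diagnostics):
        self.diagnostics = dict(diagnostics)
        msgs = "; ".join(f"{k}: {v}" for k, v in self.diagnostics.items())
        super().__init__(f"no analyzable channel ({msgs})")
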