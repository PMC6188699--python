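"""Exception hierarchy shared by all ionprobe modules."""


class IonprobeError(Exception):
    """Base class for all package errors."""


class FormatError(IonprobeError):
    """A file could not be parsed in the declared dialect/format."""


class ValidationError(IonprobeError):
    """Parsed data violates a documented invariant."""


class FitError(IonprobeError):
    """An optimization failed; carries the last iterate when available."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
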