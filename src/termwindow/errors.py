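"""Exception hierarchy shared across the package."""


class TermwindowError(Exception):
    """Base class for all package errors."""


class ValidationError(TermwindowError, ValueError):
    """Invalid argument, configuration, or data structure."""


class PlacementError(ValidationError):
    """A simulated unit could not be placed on any chromosome."""


class TrackIOError(TermwindowError):
    """Failure reading or writing a coverage/annotation file."""
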