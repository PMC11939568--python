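"""Exception hierarchy shared across the package."""


class EmospatError(Exception):
    """Base class for all package errors."""


class LexiconParseError(EmospatError):
    """A lexicon/modifier/emoji file could not be parsed; names the line."""

    def __init__(self, path, lineno, message):
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class ValidationError(EmospatError):
    """An entry or configuration violates an invariant."""


class DegenerateInputError(EmospatError):
    """A statistic was requested on input with zero variance."""


class StageSegmentationError(EmospatError):
    """The automatic stage rule could not place both breaks.

    Callers can always supply ``manual_breaks`` instead.
    """


class UnknownRegionError(EmospatError):
    """Posts reference region codes absent from the region set."""

    def __init__(self, offenders):
        self.offenders = sorted(offenders)
        super().__init__(
            "unknown region code(s): " + ", ".join(map(str, self.offenders))
        )
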