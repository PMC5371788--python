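"""Exception hierarchy shared across the package."""


class StitchkitError(Exception):
    """Base class for all stitchkit errors."""


class MalformedFastaError(StitchkitError):
    """Input text is not parseable FASTA (e.g. missing header line)."""


class MultipleRecordsError(StitchkitError):
    """More than one record where exactly one sequence is required."""


class InvalidAlphabetError(StitchkitError):
    """Sequence contains characters outside the accepted DNA alphabet."""


class ParameterError(StitchkitError):
    """A design parameter is out of range or inconsistent."""


class DesignFailureError(StitchkitError):
    """No candidate passed the filters; message describes the best near-miss."""


class UnknownOverlapError(StitchkitError, KeyError):
    """Requested overlap fragment is not in the library."""

    def __init__(self, name: str, valid: list[str]):
        self.name = name
        self.valid = valid
        super().__init__(
            f"unknown overlap fragment {name!r}; valid names: {', '.join(valid)}"
        )

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]
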