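"""Exception hierarchy shared across the package."""


class SromicsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SromicsError, ValueError):
    """Invalid user input: bad data, bad configuration, missing columns."""


class ParseError(ValidationError):
    """Malformed model-form string.

    Carries the character ``position`` at which parsing failed.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class FitDivergenceError(SromicsError):
    """Gradient descent produced a non-finite loss or gradient.

    Callers running a population search catch this and discard the model.
    """


class SearchError(SromicsError):
    """The evolutionary search could not produce any valid fitted model."""
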