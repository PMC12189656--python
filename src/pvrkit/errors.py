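"""Exception types shared across the toolkit."""


class ValidationError(ValueError):
    """A domain object violated one of its invariants."""


class InsufficientDataError(RuntimeError):
    """Too few usable beats (or records) to produce a reliable summary."""


class CalibrationError(RuntimeError):
    """Truncated-normal moment matching could not reach the requested moments."""


class ParseError(ValueError):
    """A file did not conform to the expected schema; carries location info."""
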