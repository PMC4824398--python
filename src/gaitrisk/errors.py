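"""Exception types raised across the pipeline."""


class ParseError(ValueError):
    """A trial file is malformed; the message names the file and line."""


class IntegrityError(ValueError):
    """Streams that must agree (e.g. lengths) do not."""


class InsufficientSignalError(ValueError):
    """Too little signal to compute the requested quantity."""


class DegenerateSignalError(ValueError):
    """Signal is constant or otherwise carries no usable structure."""
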