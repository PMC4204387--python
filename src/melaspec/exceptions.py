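"""Exception hierarchy for melaspec."""


class MelaspecError(Exception):
    """Base class for all melaspec errors."""


class ValidationError(MelaspecError, ValueError):
    """A parameter or input object violates a documented precondition."""


class FormatError(MelaspecError, ValueError):
    """A file on disk does not match the declared layout or schema."""


class DegenerateScanError(MelaspecError, ValueError):
    """A scan is constant, so min-max normalization is undefined."""
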