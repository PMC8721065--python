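class RankAgreeError(Exception):
    """Base class for all package errors."""


class ValidationError(RankAgreeError):
    """Invalid input data, scale definition, or study design."""
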