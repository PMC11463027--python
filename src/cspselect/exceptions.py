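"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented contract (shapes, labels, ranges)."""


class FormatError(ValidationError):
    """A session container is malformed; the message names the missing field."""


class ChannelLookupError(ValidationError):
    """A requested channel name cannot be resolved in the target montage."""


class NoCandidatesError(RuntimeError):
    """Pattern-threshold extraction produced no combination large enough to
    evaluate; callers should fall back to a baseline."""
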