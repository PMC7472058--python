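"""Exception hierarchy shared across the pipeline."""


class ActichildError(Exception):
    """Base class for all package errors."""


class FormatError(ActichildError):
    """A file or value does not conform to the documented format."""


class IntegrityError(ActichildError):
    """Data are syntactically valid but internally inconsistent."""


class UsageError(ActichildError):
    """An operation was called with arguments that violate its contract."""
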