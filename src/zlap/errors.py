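"""Exception types shared across the pipeline."""


class ZlapError(Exception):
    """Base class for pipeline errors."""


class InputError(ZlapError, ValueError):
    """Malformed or inconsistent input data (unreadable image, ragged streams...)."""


class SchemaError(ZlapError, ValueError):
    """A table does not conform to the expected column schema."""


class LayoutError(ZlapError, ValueError):
    """Detected well geometry is inconsistent with the declared plate layout."""


class ConfigError(ZlapError, ValueError):
    """Invalid stimulus-schedule or run configuration."""
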