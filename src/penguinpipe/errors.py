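"""Exception hierarchy shared across the pipeline stages."""


class PenguinPipeError(Exception):
    """Base class for all pipeline errors."""


class ImageRefParseError(PenguinPipeError, ValueError):
    """An image identifier string does not follow SITExYEARx_imagenumber."""


class SchemaError(PenguinPipeError, ValueError):
    """A table is missing required columns or has an unknown layout."""


class ValidationError(PenguinPipeError, ValueError):
    """A table row holds a value outside its documented domain."""


class ConfigError(PenguinPipeError, ValueError):
    """A configuration value (threshold, window, scenario) is invalid."""


class FormatError(PenguinPipeError, ValueError):
    """A matrix/density file cannot be interpreted unambiguously."""
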