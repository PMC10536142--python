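"""Exception types shared across the package."""


class RehabbandError(Exception):
    """Base class for all package-specific errors."""


class InputError(RehabbandError, ValueError):
    """Invalid user-supplied data (wrong shape, missing class, short stream...)."""


class DegenerateInputError(InputError):
    """Input is structurally valid but carries no usable signal (zero range, zero baseline)."""


class StateError(RehabbandError, RuntimeError):
    """Operation requires a fitted/initialized component that is missing."""


class BundleLoadError(RehabbandError, ValueError):
    """A serialized model bundle is truncated, corrupted or internally inconsistent."""
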