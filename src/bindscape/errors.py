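"""Exception types shared across the package."""


class BindscapeError(Exception):
    """Base class for all package-specific errors."""


class LandscapeError(BindscapeError, ValueError):
    """Invalid landscape parameters (non-positive roughness, entropy, ...)."""


class DegenerateSpectrumError(BindscapeError, ValueError):
    """A spectrum statistic is undefined (e.g. zero non-native spread)."""


class ProfileError(BindscapeError, ValueError):
    """A free-energy profile is malformed or too short to use."""


class FitError(BindscapeError, ValueError):
    """Distribution fitting cannot proceed on the given sample."""


class ConfigError(BindscapeError, ValueError):
    """Invalid pipeline configuration; message names the offending key."""
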