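"""Exception hierarchy shared across the package."""


class ScintidoseError(Exception):
    """Base class for all scintidose errors."""


class CurveError(ScintidoseError, ValueError):
    """Invalid curve data or a curve metric that cannot be evaluated."""


class ParseError(ScintidoseError, ValueError):
    """Malformed pulse/curve CSV or sidecar file."""


class ConfigError(ScintidoseError, ValueError):
    """Invalid run configuration."""
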