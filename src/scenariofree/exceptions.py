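"""Exception hierarchy shared across the package."""


class ScenarioFreeError(Exception):
    """Base class for all package errors."""


class ValidationError(ScenarioFreeError, ValueError):
    """Invalid argument values or inconsistent object state."""


class GeometryError(ScenarioFreeError, ValueError):
    """Geometric impossibility (target outside grid, beam missing the grid, ...)."""


class NumericalError(ScenarioFreeError, ArithmeticError):
    """A numerically degenerate situation (all-zero densities, PSD violation, ...)."""


class ConfigError(ScenarioFreeError, ValueError):
    """Malformed run configuration."""
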