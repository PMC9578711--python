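"""Exception hierarchy for the macroflim pipeline."""


class MacroflimError(Exception):
    """Base class for all macroflim errors."""


class ParameterError(MacroflimError, ValueError):
    """A model or configuration parameter violates its invariants."""


class DomainError(MacroflimError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class InsufficientPhotonsError(MacroflimError):
    """A decay histogram carries too few photons to be fitted reliably."""


class ConvergenceError(MacroflimError):
    """The nonlinear optimiser failed; carries the last iterate if available."""

    def __init__(self, message, last_fit=None):
        super().__init__(message)
        self.last_fit = last_fit


class PlacementError(MacroflimError):
    """Synthetic cells could not be placed without overlap."""


class ScheduleError(MacroflimError, ValueError):
    """An injection schedule is not strictly increasing or is incomplete."""


class PhaseCoverageError(MacroflimError):
    """A flux phase contains no (or too few) measurements."""


class ClassCoverageError(MacroflimError):
    """Fewer than two phenotype classes are present where both are required."""


class StratificationError(MacroflimError):
    """A class has too few rows to support a stratified split."""


class ConfigError(MacroflimError, ValueError):
    """A pipeline configuration document failed validation."""
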