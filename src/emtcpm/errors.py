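"""Exception hierarchy for the simulator."""


class EmtCpmError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EmtCpmError, ValueError):
    """A numeric argument is outside its admissible range."""


class ConfigurationError(EmtCpmError, ValueError):
    """A scenario or Potts configuration is internally inconsistent."""


class DomainError(EmtCpmError, ValueError):
    """A state passed to the kinetics is outside the model domain."""


class IntegrationError(EmtCpmError, RuntimeError):
    """The ODE integrator failed (step collapse); carries the cell id if known."""

    def __init__(self, message, cell_id=None):
        super().__init__(message)
        self.cell_id = cell_id


class AnalysisError(EmtCpmError, RuntimeError):
    """A numerical analysis (root finding, plateau detection) found no answer."""


class LifecycleError(EmtCpmError, RuntimeError):
    """A registry call happened out of order (e.g. stepping before init)."""


class ModelFormatError(EmtCpmError, ValueError):
    """A model definition file could not be parsed."""


class UnsupportedSBMLError(ModelFormatError):
    """The SBML file uses constructs outside the supported subset."""
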