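"""Exception hierarchy for npmicroenv."""


class NPMicroenvError(Exception):
    """Base class for all package errors."""


class InvalidEnvironmentError(NPMicroenvError, ValueError):
    """A gas environment with unphysical pressures or fractions."""


class DomainError(NPMicroenvError, ValueError):
    """A rate law or kinetic function was called outside its domain."""


class ScenarioError(NPMicroenvError, ValueError):
    """A culture scenario violates its invariants."""


class ScenarioLookupError(ScenarioError, KeyError):
    """An unknown scenario id was requested from the registry."""


class GeometryError(NPMicroenvError, ValueError):
    """A construct does not fit inside its vessel, or a mesh cannot be built."""


class SolverError(NPMicroenvError, RuntimeError):
    """The transient or steady solver failed to converge."""


class ReportingError(NPMicroenvError, ValueError):
    """A summary was requested over an empty region or outside the horizon."""
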