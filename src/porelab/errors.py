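"""Exception hierarchy for porelab.

Every reader rejects, never silently repairs, an invariant violation; the
exception type says which contract was broken.
"""


class PorelabError(Exception):
    """Base class for all porelab errors."""


class ParseError(PorelabError):
    """A field in an input file could not be parsed; message names the line."""


class ValidationError(PorelabError):
    """A parsed object violates a type invariant (e.g. duplicate atom id)."""


class TopologyError(ValidationError):
    """Particle set differs between trajectory frames."""


class OrderingError(ValidationError):
    """Frame indices are not strictly increasing."""


class HeaderError(ParseError):
    """Required header metadata is missing or malformed."""


class SamplingError(ValidationError):
    """Trace timestamps deviate from uniform sampling."""


class MetadataError(PorelabError):
    """An operation needs metadata (box, voltage, dt) the input lacks."""


class InputError(PorelabError):
    """Operation precondition violated (bad parameter, empty selection...)."""


class StabilityError(InputError):
    """A simulation step size is too large for the integrator/unwrapping."""


class BaselineError(PorelabError):
    """No dominant baseline mode could be identified in a current trace."""


class InsufficientDataError(InputError):
    """Too few events/frames for the requested estimator."""
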