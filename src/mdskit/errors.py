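"""Exception hierarchy shared by all mdskit modules."""


class MDSKitError(Exception):
    """Base class for all mdskit errors."""


class InputError(MDSKitError, ValueError):
    """Malformed user input (bad symbol, wrong length, bad file line)."""


class PreconditionError(MDSKitError, ValueError):
    """An operation was called on a set that violates its precondition."""


class StateError(MDSKitError, RuntimeError):
    """The object is in a state where the operation is undefined
    (e.g. longest-path query on a graph that still has a cycle)."""


class ResourceLimitError(MDSKitError, RuntimeError):
    """An enumeration would materialize more objects than the configured cap."""


class InvariantError(MDSKitError, RuntimeError):
    """An internal structural invariant failed; indicates a bug (or a
    falsified structural property) and must never be silently ignored."""


class ConstructionError(MDSKitError, RuntimeError):
    """A set construction could not be completed (no valid completion found)."""
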