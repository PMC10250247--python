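"""Exception hierarchy.

``ValidationError`` covers malformed inputs and contract violations;
``EmptyNetworkError`` marks the distinct "nothing to analyze" outcome
(no reachable targets, no external signals) so callers and the CLI can
treat it differently from bad input; ``StateError`` flags operations
invoked on objects that are not yet in the required state.
"""


class ExsignetError(Exception):
    """Base class for all package errors."""


class ValidationError(ExsignetError, ValueError):
    """Input or invariant violation."""


class EmptyNetworkError(ExsignetError, RuntimeError):
    """A requested network is empty (no targets reachable / no external signals)."""


class StateError(ExsignetError, RuntimeError):
    """Operation requires state that has not been populated yet."""
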