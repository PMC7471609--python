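"""Exception hierarchy shared across the toolbox."""


class FluxkitError(Exception):
    """Base class for all fluxkit errors."""


class ModelStructureError(FluxkitError):
    """A model invariant is violated (dangling reference, bad bounds, ...)."""


class GPRParseError(FluxkitError):
    """A gene-protein-reaction string could not be parsed.

    Carries ``position``, the character offset of the offending token.
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class UnknownIdentifierError(FluxkitError, KeyError):
    """Lookup of a gene/reaction/metabolite id that does not exist."""


class InfeasibleError(FluxkitError):
    """The feasible flux space is empty under the given bounds."""


class UnboundedError(FluxkitError):
    """The LP objective is unbounded; ``reactions`` names candidate directions."""

    def __init__(self, message: str, reactions: tuple[str, ...] = ()):
        super().__init__(message)
        self.reactions = reactions


class BalanceError(FluxkitError):
    """A reaction imbalance cannot be corrected with protons and water.

    Carries ``residual``, the per-element/charge deltas that remain.
    """

    def __init__(self, message: str, residual: dict | None = None):
        super().__init__(message)
        self.residual = residual or {}
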