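"""Exception hierarchy for induceopt."""


class InduceOptError(Exception):
    """Base class for all induceopt errors."""


class DomainError(InduceOptError, ValueError):
    """An input is outside its allowed domain (e.g. a dose fraction not in [0, 100])."""


class RecipeError(InduceOptError, ValueError):
    """A mix recipe is internally inconsistent or cannot realise the requested dose."""


class LayoutError(InduceOptError, ValueError):
    """Dose list does not match the plate's culture-well layout."""


class StateError(InduceOptError, RuntimeError):
    """An operation was called in a state that cannot support it (e.g. fitting on no data)."""


class StoreFormatError(InduceOptError, ValueError):
    """A persisted run store is missing or corrupt."""


class RunError(InduceOptError, RuntimeError):
    """A closed-loop run aborted; carries the partial provenance store."""

    def __init__(self, message: str, partial_store=None):
        super().__init__(message)
        self.partial_store = partial_store
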