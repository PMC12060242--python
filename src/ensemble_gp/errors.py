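"""Exception hierarchy shared across the package."""


class EnsembleGPError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EnsembleGPError, ValueError):
    """A parameter is outside its documented domain."""


class SchemaError(EnsembleGPError, ValueError):
    """Shapes, column order, or identifiers do not line up."""


class EmptyPanelError(EnsembleGPError, ValueError):
    """An operation would leave no markers."""


class ContractError(EnsembleGPError, TypeError):
    """An operation received a fitted model of the wrong kind."""


class ReferentialIntegrityError(EnsembleGPError, KeyError):
    """A record references an id that does not exist."""


class UndefinedMetricError(EnsembleGPError, ValueError):
    """A metric is undefined on this input (e.g. constant vector)."""
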