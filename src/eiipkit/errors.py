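"""Exception hierarchy.

Two broad classes matter for the CLI exit-code contract: configuration /
usage problems (exit 1) and data problems (exit 2).
"""


class EiipkitError(Exception):
    """Base class for all package errors."""


class ConfigError(EiipkitError):
    """Invalid configuration (bad YAML keys, bad valence table file, ...)."""


class DataError(EiipkitError):
    """Invalid input data (formulas, tables, plates)."""


class FormulaError(DataError):
    """Malformed molecular formula; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class UnknownElementError(FormulaError):
    """Token looks like an element symbol but is not one."""

    def __init__(self, symbol: str, position: int | None = None):
        self.symbol = symbol
        super().__init__(f"unknown element {symbol!r}", position)


class MissingEntryError(DataError):
    """An element has no entry in a valence or mass table."""

    def __init__(self, element: str, table: str):
        self.element = element
        super().__init__(f"element {element!r} has no entry in {table}")


class StructureBackendUnavailable(ConfigError):
    """rdkit is not installed; user should supply a molecular formula."""


class StructureError(DataError):
    """Line notation could not be parsed by the structure backend."""


class PlateError(DataError):
    """Malformed or incomplete plate assay."""


class NoTransitionError(DataError):
    """Dose-response data show no transition through 50% inhibition."""
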