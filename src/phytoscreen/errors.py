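"""Exception hierarchy shared by all pipeline stages."""


class PhytoscreenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PhytoscreenError):
    """An input table is missing a required column."""


class TableParseError(PhytoscreenError):
    """A table cell could not be interpreted; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class StructureParseError(PhytoscreenError):
    """A structure file (PDB/PDBQT/XYZ) could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class UnknownElementError(PhytoscreenError):
    """An element symbol is not covered by the requested parameter table."""


class DegenerateInputError(PhytoscreenError):
    """Input is formally valid but makes the requested quantity undefined
    (zero total area, non-positive control absorbance, zero slope...)."""


class InsufficientDataError(PhytoscreenError):
    """Too few observations for the requested fit or sampling."""
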