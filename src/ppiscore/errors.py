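"""Exception hierarchy.

Each public failure mode gets its own class so the CLI can map them to
distinct exit codes and callers can catch precisely.
"""


class PPIScoreError(Exception):
    """Base class for all package errors."""


class FormatError(PPIScoreError):
    """Input file could not be parsed (PDB, matrix, or score table)."""


class EmptyStructureError(PPIScoreError):
    """No polymer residues remain after filtering."""


class NoInterfaceError(PPIScoreError):
    """No inter-chain contacts exist at the requested threshold."""


class ParameterError(PPIScoreError):
    """A parameter is outside its allowed set (e.g. distance threshold)."""


class PotentialFormatError(FormatError):
    """Scoring-matrix directory is malformed (dimensions, symmetry, parse)."""


class DegenerateBackgroundError(PPIScoreError):
    """Background score distribution has zero variance; Z is undefined."""
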