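"""Exception hierarchy shared across the pipeline.

The command-line driver maps these onto exit codes: configuration problems
exit 2, data/format problems exit 3, numerical failures exit 4.
"""


class EnsembleCDError(Exception):
    """Base class for all package errors."""


class ConfigError(EnsembleCDError):
    """Invalid or inconsistent run configuration."""


class DataError(EnsembleCDError):
    """Problem with input data (files, topologies, selections)."""


class FormatError(DataError):
    """Unreadable or unsupported file content."""


class StructuralError(DataError):
    """Topology/coordinate inconsistency (atom counts, mismatched models)."""


class SelectionError(DataError):
    """Atom selection is empty or refers to unknown atoms."""


class NumericalError(EnsembleCDError):
    """Numerical failure (rank deficiency, insufficient data, degenerate grid)."""


class InsufficientDataError(NumericalError):
    """Too few frames/points for the requested analysis."""
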