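"""Typed errors raised across the pipeline.

Every error a caller may want to handle programmatically derives from
:class:`EdgeQNetError`; the CLI maps them to exit status 1 with the error
class name on stderr.
"""

from __future__ import annotations


class EdgeQNetError(Exception):
    """Base class for all edgeqnet errors."""


class FormatError(EdgeQNetError):
    """Malformed input table (bad value, bad column set, bad state code...)."""


class DuplicateMoleculeError(FormatError):
    """A molecule id appears more than once within one expression layer."""

    def __init__(self, molecule_id: str, message: str | None = None):
        self.molecule_id = molecule_id
        super().__init__(message or f"duplicate molecule id: {molecule_id!r}")


class MissingSampleError(EdgeQNetError):
    """A manifest references a sample whose files are absent, or lists none."""


class ModelIOError(EdgeQNetError):
    """Model file missing, corrupted, or of an unsupported schema version."""


class ConfigError(EdgeQNetError):
    """Invalid configuration value."""


class DegenerateStateError(EdgeQNetError):
    """A state group is too small (or unknown) for the requested statistic."""


class DegenerateMoleculeError(EdgeQNetError):
    """A molecule has zero variance in a state where standardization is needed."""

    def __init__(self, molecule_id: str, state: int, message: str | None = None):
        self.molecule_id = molecule_id
        self.state = state
        super().__init__(
            message
            or f"molecule {molecule_id!r} has zero standard deviation in state {state}"
        )


class DegenerateInputError(EdgeQNetError):
    """Input vector unusable for the statistic (too short, zero variance)."""


class MissingMoleculeError(EdgeQNetError):
    """A profile or edge vector lacks molecules/features the operation needs."""

    def __init__(self, missing, message: str | None = None):
        self.missing = sorted(missing)
        super().__init__(message or f"missing molecules/features: {self.missing}")


class EmptyFeatureSetError(EdgeQNetError):
    """No feature survived filtering / every candidate fit was empty."""

    def __init__(self, message: str, trace=None):
        self.trace = trace
        super().__init__(message)
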