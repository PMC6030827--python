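"""Exception hierarchy.

All library-specific failures derive from :class:`TissueNetsError` so callers
(and the CLI) can distinguish data errors from programming errors.
"""


class TissueNetsError(Exception):
    """Base class for all tissuenets errors."""


class FormatError(TissueNetsError, ValueError):
    """A file violates its format contract (carries the offending line number)."""

    def __init__(self, message, path=None, line=None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ConflictError(FormatError):
    """The same gene pair appears twice with contradictory weights."""


class DuplicateError(FormatError):
    """A gene (row) appears more than once where uniqueness is required."""


class InsufficientSamplesError(FormatError):
    """An expression matrix has fewer samples than correlation requires."""


class EmptyTissueError(TissueNetsError):
    """A tissue ends up with zero expressed/annotated genes."""


class EmptyStandardError(TissueNetsError):
    """A gold standard has no positives (nothing to train on)."""


class InsufficientLabelsError(TissueNetsError):
    """Too few positive or negative labels for five-fold cross-validation."""


class UndefinedMetricError(TissueNetsError):
    """An evaluation metric is undefined (e.g. no truth genes were scored)."""


class EmptyQueryError(TissueNetsError):
    """No query gene is present in the network."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            "no query gene present in network; missing: " + ", ".join(self.missing)
        )


class LabelCollisionError(TissueNetsError):
    """Two subnetwork views carry the same tissue label."""


class DomainError(TissueNetsError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class SimulationSpecError(TissueNetsError, ValueError):
    """A simulation specification violates its invariants."""
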