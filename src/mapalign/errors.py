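"""Exception hierarchy for mapalign.

The CLI maps :class:`ConfigurationError` to exit code 2 and
:class:`DataError` to exit code 3; everything else is a bug.
"""


class MapAlignError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MapAlignError):
    """Invalid or inconsistent user configuration (missing column, bad key...)."""


class DataError(MapAlignError):
    """Input data unusable (empty file, too few anchors...)."""


class IntegrityError(MapAlignError):
    """Internal referential integrity violated (dangling feature id...)."""


class AlignmentFailedError(MapAlignError):
    """RANSAC could not find enough inliers; caller should fall back to identity."""


class SizeLimitError(MapAlignError):
    """A component exceeds the enumeration guard; use segmentation or VLSNS."""


class InfeasibleSolutionError(MapAlignError):
    """A candidate solution violates the assignment-problem constraints."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("infeasible solution: " + "; ".join(self.violations))
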