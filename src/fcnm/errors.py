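"""Exception hierarchy for the fcnm package.

Every error raised deliberately by this package derives from
:class:`FCNMError`, so callers can catch pipeline failures without
swallowing programming errors.
"""

from __future__ import annotations


class FCNMError(Exception):
    """Base class for all fcnm errors."""


class InvalidArgumentError(FCNMError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class OutOfGridError(FCNMError):
    """A world coordinate maps to a voxel index outside the grid bounds."""

    def __init__(self, xyz_mm, index, shape):
        self.xyz_mm = tuple(float(v) for v in xyz_mm)
        self.index = tuple(int(v) for v in index)
        self.shape = tuple(int(v) for v in shape)
        super().__init__(
            f"world coordinate {self.xyz_mm} mm -> voxel {self.index} "
            f"outside grid of shape {self.shape}"
        )


class GridMismatchError(FCNMError):
    """Two objects that must share a voxel grid do not."""


class FormatError(FCNMError):
    """A file on disk does not match the declared or expected format."""


class SchemaError(FormatError):
    """A tabular input is missing required columns."""


class TableParseError(FormatError):
    """One or more rows of a contrast table failed to parse.

    Carries the individual row problems so they can be reported together.
    """

    def __init__(self, row_errors):
        self.row_errors = list(row_errors)
        lines = "; ".join(self.row_errors[:10])
        more = "" if len(self.row_errors) <= 10 else f" (+{len(self.row_errors) - 10} more)"
        super().__init__(f"{len(self.row_errors)} bad row(s): {lines}{more}")


class EmptySphereError(FCNMError):
    """A seed sphere contains no voxel of the grid."""

    def __init__(self, center_mm):
        self.center_mm = tuple(float(v) for v in center_mm)
        super().__init__(f"sphere at {self.center_mm} mm covers no voxel of the grid")


class EmptySeedError(FCNMError):
    """A contrast seed is empty after gray-matter masking."""


class MissingDataError(FCNMError):
    """Required auxiliary data (e.g. motion parameters) are absent."""


class DegenerateDesignError(FCNMError):
    """A confound design is unusable (e.g. every frame is a spike)."""


class DegenerateSeedError(FCNMError):
    """A seed time course is constant and cannot be correlated."""


class InsufficientDataError(FCNMError):
    """Too few observations for the requested statistic."""
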