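"""Spatial containers: scalar images and integer label masks with physical spacing.

Arrays are indexed ``(row, col[, slice])``, 0-based; spacing is carried
separately, in millimetres per axis, and all metric computations are done in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import validate_labels


def _check_spacing(spacing, ndim: int) -> tuple[float, ...]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != ndim:
        raise ValueError(f"spacing has {len(sp)} components for a {ndim}-D array")
    if any(s <= 0 for s in sp):
        raise ValueError(f"all spacing components must be positive, got {sp}")
    return sp


@dataclass
class ImageGrid:
    """A 2-D or 3-D scalar image plus per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, ...] = field(default=(1.0, 1.0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"ImageGrid must be 2-D or 3-D, got ndim={self.data.ndim}")
        self.spacing = _check_spacing(self.spacing, self.data.ndim)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def voxel_volume_mm3(self) -> float:
        """Product of the spacing components (an area for 2-D grids)."""
        return float(np.prod(self.spacing))


@dataclass
class LabelMask:
    """Integer-labelled grid aligned with an :class:`ImageGrid`."""

    data: np.ndarray
    spacing: tuple[float, ...] = field(default=(1.0, 1.0))

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.array_equal(rounded, data):
                raise ValueError("LabelMask requires integer label values")
            data = rounded
        self.data = data.astype(np.int64)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"LabelMask must be 2-D or 3-D, got ndim={self.data.ndim}")
        self.spacing = _check_spacing(self.spacing, self.data.ndim)
        validate_labels(self.data)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def labels_present(self) -> list[int]:
        return [int(v) for v in np.unique(self.data)]
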