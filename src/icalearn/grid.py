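"""Voxel grids and masked subject scans.

All pipeline stages work on masked 2-D matrices (time x in-mask voxel);
the :class:`VolumeGrid` records how those flat feature positions map back
onto a 3-D volume so maps can be exported as NIfTI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel grid with a boolean brain mask.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis, e.g. ``(12, 12, 8)``.
    mask : ndarray of bool, shape ``shape``
        In-mask voxels; flattened (C order) positions of the True voxels
        define the feature order of every V-length vector in the pipeline.
    """

    shape: tuple[int, int, int]
    mask: np.ndarray = field(repr=False)

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(self.shape):
            raise ValueError(f"mask shape {mask.shape} != grid shape {self.shape}")
        if not mask.any():
            raise ValueError("mask must contain at least one voxel")
        object.__setattr__(self, "mask", mask)

    @classmethod
    def full(cls, shape: tuple[int, int, int]) -> "VolumeGrid":
        """Grid whose mask covers every voxel."""
        return cls(tuple(shape), np.ones(shape, dtype=bool))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_index(self) -> np.ndarray:
        """(V, 3) integer coordinates of in-mask voxels, C order."""
        return np.argwhere(self.mask)

    def unmask(self, values: np.ndarray) -> np.ndarray:
        """Scatter a (..., V) array back into a (..., *shape) volume (zeros outside)."""
        values = np.asarray(values)
        out = np.zeros(values.shape[:-1] + tuple(self.shape), dtype=values.dtype)
        out[..., self.mask] = values
        return out

    def apply_mask(self, volume: np.ndarray) -> np.ndarray:
        """Extract the V in-mask values of a (..., *shape) volume."""
        return np.asarray(volume)[..., self.mask]

    def __eq__(self, other):
        return (
            isinstance(other, VolumeGrid)
            and tuple(self.shape) == tuple(other.shape)
            and np.array_equal(self.mask, other.mask)
        )

    def __hash__(self):
        return hash((tuple(self.shape), self.mask.tobytes()))


@dataclass
class SubjectScan:
    """One subject's masked BOLD-like data matrix plus metadata.

    ``data`` is T x V (time points by in-mask voxels); ``group`` is one of
    ``"SZ"``, ``"HC"`` or ``"unknown"``; ``site`` is a free-form site id.
    """

    subject_id: str
    group: str
    site: str
    data: np.ndarray
    grid: VolumeGrid

    VALID_GROUPS = ("SZ", "HC", "unknown")

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.group not in self.VALID_GROUPS:
            raise ValueError(f"group must be one of {self.VALID_GROUPS}, got {self.group!r}")
        if self.data.ndim != 2:
            raise ValueError("scan data must be 2-D (time x voxel)")
        if self.data.shape[0] < 2:
            raise ValueError("scan needs at least 2 time points")
        if self.data.shape[1] != self.grid.n_voxels:
            raise ValueError(
                f"scan has {self.data.shape[1]} voxels, grid mask has {self.grid.n_voxels}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError(f"non-finite values in scan {self.subject_id!r}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]
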