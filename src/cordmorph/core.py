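"""Shared grid containers for the cord pipeline.

Axis convention used throughout the package (documented in every output
header):

* axis 0 — right -> left (``i``)
* axis 1 — anterior -> posterior (``j``)
* axis 2 — inferior -> superior (``k``); slice 0 is the most inferior slice

Voxel indices are 0-based.  Physical coordinates are voxel index times the
per-axis voxel size in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CordVolume", "CordMask", "AXIS_RL", "AXIS_AP", "AXIS_IS"]

AXIS_RL = 0
AXIS_AP = 1
AXIS_IS = 2


def _as_voxel_mm(voxel_mm) -> tuple[float, float, float]:
    if np.isscalar(voxel_mm):
        voxel_mm = (float(voxel_mm),) * 3
    voxel_mm = tuple(float(v) for v in voxel_mm)
    if len(voxel_mm) != 3:
        raise ValueError("voxel_mm must be a scalar or a 3-tuple")
    if any(v <= 0 for v in voxel_mm):
        raise ValueError("voxel sizes must be > 0")
    return voxel_mm


@dataclass
class CordVolume:
    """A 3D intensity grid with its voxel spacing.

    Parameters
    ----------
    data:
        3D float array, axes ``(R-L, A-P, I-S)``.
    voxel_mm:
        Per-axis voxel size in mm (scalar means isotropic).
    """

    data: np.ndarray
    voxel_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        self.voxel_mm = _as_voxel_mm(self.voxel_mm)
        if not np.isfinite(self.data).all():
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[AXIS_IS]


@dataclass
class CordMask:
    """A 3D binary cord mask on the same grid as its volume."""

    data: np.ndarray
    voxel_mm: tuple[float, float, float]
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask data must be 3D")
        self.voxel_mm = _as_voxel_mm(self.voxel_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[AXIS_IS]

    def slice_areas_mm2(self) -> np.ndarray:
        """Per-slice area: voxel count times the in-plane voxel area."""
        vx, vy, _ = self.voxel_mm
        return self.data.sum(axis=(AXIS_RL, AXIS_AP)).astype(float) * vx * vy

    def nonempty_slices(self) -> np.ndarray:
        return self.data.any(axis=(AXIS_RL, AXIS_AP))
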