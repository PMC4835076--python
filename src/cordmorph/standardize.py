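"""Cord straightening and length standardization.

Straightening translates each axial slice by an integer number of voxels so
its center of mass lands on the common in-plane grid center; translation
preserves per-slice areas exactly.  Length standardization resamples the
straightened stack to a common slice count with nearest-neighbour
interpolation along the inferior-superior axis, so binary values are
preserved exactly.  The common slice count for a cohort is the (lower)
median of the per-subject counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CordMask

__all__ = [
    "Centerline",
    "straighten",
    "standardize_length",
    "cohort_standard_length",
    "STANDARD_LENGTH",
]

STANDARD_LENGTH = 413


@dataclass
class Centerline:
    """Per-slice in-plane center of mass of the cord, in mm."""

    x_mm: np.ndarray
    y_mm: np.ndarray

    def __post_init__(self) -> None:
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        if self.x_mm.shape != self.y_mm.shape:
            raise ValueError("centerline coordinate arrays must match")
        if not (np.isfinite(self.x_mm).all() and np.isfinite(self.y_mm).all()):
            raise ValueError("centerline must be finite")


def straighten(mask: CordMask) -> tuple[CordMask, Centerline]:
    """Translate each slice so its center of mass sits at the grid center.

    Shifts are integer voxel counts (area is preserved exactly); the
    returned :class:`Centerline` is the original, pre-straightening one.
    A slice whose shift would push mask voxels out of the field of view, or
    an empty slice, is an error — upstream QC should have caught both.
    """
    data = mask.data
    nx, ny, nz = data.shape
    vx, vy, _ = mask.voxel_mm
    ci, cj = nx // 2, ny // 2

    out = np.zeros_like(data)
    xs = np.empty(nz)
    ys = np.empty(nz)
    for z in range(nz):
        sl = data[:, :, z]
        if not sl.any():
            raise ValueError(f"slice {z} is empty; cannot straighten")
        com_i, com_j = ndimage.center_of_mass(sl)
        xs[z] = com_i * vx
        ys[z] = com_j * vy
        di = ci - int(round(com_i))
        dj = cj - int(round(com_j))
        ii, jj = np.nonzero(sl)
        ii = ii + di
        jj = jj + dj
        if ii.min() < 0 or ii.max() >= nx or jj.min() < 0 or jj.max() >= ny:
            raise ValueError(
                f"slice {z}: straightening shift ({di}, {dj}) pushes the mask "
                "outside the field of view"
            )
        out[ii, jj, z] = True

    return CordMask(out, mask.voxel_mm, qc=dict(mask.qc)), Centerline(xs, ys)


def _nn_slice_index(L: int, N: int) -> np.ndarray:
    """Nearest-neighbour source slice for each of L output slices.

    Output slice k maps to input slice round(k*(N-1)/(L-1)); exact .5 ties
    round toward the inferior (smaller) index for bit-reproducibility.
    """
    if L == 1:
        return np.zeros(1, dtype=int)
    x = np.arange(L) * (N - 1) / (L - 1)
    return np.ceil(x - 0.5).astype(int)


def standardize_length(mask: CordMask, L: int = STANDARD_LENGTH) -> CordMask:
    """Resample the stack to exactly ``L`` slices (nearest neighbour in z)."""
    if L < 2:
        raise ValueError("standard length must be >= 2")
    N = mask.n_slices
    idx = _nn_slice_index(L, N)
    out = CordMask(mask.data[:, :, idx], mask.voxel_mm, qc=dict(mask.qc))
    out.qc["standardized_from_slices"] = int(N)
    return out


def cohort_standard_length(masks: list[CordMask] | list[int]) -> int:
    """Lower median of per-subject slice counts (an observed length)."""
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    lengths = sorted(
        m if isinstance(m, (int, np.integer)) else m.n_slices for m in masks
    )
    return int(lengths[(len(lengths) - 1) // 2])
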