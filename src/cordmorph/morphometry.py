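"""Radial-distance and cross-sectional-area profiles of a standardized mask.

Radial distances are measured per axial slice by casting rays from the
slice's center of mass, one every 5 degrees (72 per slice), stepping 0.1
voxel along each ray and recording the distance of the first inside ->
outside transition.  Angle convention (written into every output header):
0 deg points anterior, angles increase counterclockwise when viewed from
superior (90 deg = subject's left); one column per 5 deg.

Cross-sectional area is the voxel count of the slice times the in-plane
voxel area.

Vertebral levels C2..C7 are assigned to slice intervals from configurable
fractional boundaries of the C2 -> C7/T1 span (default: equal sixths);
vertebral level Ck overlies spinal segments C(k+1)-C(k+2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import CordMask

__all__ = [
    "RDProfile",
    "CSAProfile",
    "VertebralLevelMap",
    "radial_distances",
    "cross_sectional_areas",
    "label_levels",
    "N_ANGLES",
    "ANGLE_STEP_DEG",
]

ANGLE_STEP_DEG = 5.0
N_ANGLES = int(round(360.0 / ANGLE_STEP_DEG))
RAY_STEP_VOXELS = 0.1

VERTEBRAL_LEVELS = ("C2", "C3", "C4", "C5", "C6", "C7")


@dataclass
class RDProfile:
    """L x 72 radial-distance matrix in mm.

    Column ``c`` is the ray at ``5*c`` degrees; 0 deg = anterior,
    counterclockwise viewed from superior.
    """

    values: np.ndarray
    subject_id: str = ""
    qc_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_ANGLES:
            raise ValueError(f"RD profile must be L x {N_ANGLES}")
        if not np.isfinite(self.values).all() or (self.values <= 0).any():
            raise ValueError("radial distances must be finite and > 0")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(N_ANGLES) * ANGLE_STEP_DEG


@dataclass
class CSAProfile:
    """Length-L cross-sectional-area vector in mm^2."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("CSA profile must be a vector")
        if not np.isfinite(self.values).all() or (self.values <= 0).any():
            raise ValueError(
                "CSA must be finite and > 0 on every slice (empty slice?)"
            )


def _ray_directions() -> np.ndarray:
    """(72, 2) unit vectors in array axes (i = R->L, j = A->P)."""
    theta = np.deg2rad(np.arange(N_ANGLES) * ANGLE_STEP_DEG)
    # 0 deg anterior = decreasing j; 90 deg = subject-left = increasing i
    return np.column_stack([np.sin(theta), -np.cos(theta)])


def _slice_radii(sl: np.ndarray, com: tuple[float, float]) -> tuple[np.ndarray, bool]:
    """Radii (in voxels) for all 72 rays of one slice.

    The mask is sampled every 0.1 voxel along each ray with bilinear
    interpolation ('inside' = interpolated value >= 0.5, a sub-voxel border
    localization); the radius is the distance of the last inside sample of
    the first inside run.  When the center of mass itself is not inside the
    mask the slice is flagged and the radius falls back to the last inside
    sample along the ray.
    """
    from scipy.ndimage import map_coordinates

    nx, ny = sl.shape
    dirs = _ray_directions()
    # rays only need to reach the farthest mask voxel from the center
    ii, jj = np.nonzero(sl)
    r_max = float(np.hypot(np.abs(ii - com[0]).max(),
                           np.abs(jj - com[1]).max())) + 2.0
    r = np.arange(RAY_STEP_VOXELS, r_max, RAY_STEP_VOXELS)

    px = com[0] + r[None, :] * dirs[:, 0:1]
    py = com[1] + r[None, :] * dirs[:, 1:2]
    vals = map_coordinates(sl.astype(np.float32), [px.ravel(), py.ravel()],
                           order=1, mode="constant", cval=0.0)
    inside = vals.reshape(px.shape) >= 0.5

    ci, cj = int(np.floor(com[0] + 0.5)), int(np.floor(com[1] + 0.5))
    com_inside = 0 <= ci < nx and 0 <= cj < ny and bool(sl[ci, cj])
    flagged = not com_inside
    if com_inside:
        # last sample of the leading inside run (first inside -> outside)
        first_out = np.argmax(~inside, axis=1)
        first_out[inside.all(axis=1)] = len(r)
        radii = r[np.maximum(first_out - 1, 0)]
        radii[~inside[:, 0]] = RAY_STEP_VOXELS  # degenerate: starts outside
    else:
        # crescent slice: fall back to the last inside sample along the ray
        any_in = inside.any(axis=1)
        last_in = len(r) - 1 - np.argmax(inside[:, ::-1], axis=1)
        radii = np.where(any_in, r[last_in], RAY_STEP_VOXELS)
    return radii, flagged


def radial_distances(mask: CordMask, subject_id: str = "") -> RDProfile:
    """Compute the L x 72 radial-distance matrix of a standardized mask."""
    data = mask.data
    nz = data.shape[2]
    vx, vy, _ = mask.voxel_mm
    if not np.isclose(vx, vy):
        raise ValueError("radial distances require isotropic in-plane voxels")

    values = np.empty((nz, N_ANGLES))
    flags: dict[int, str] = {}
    for z in range(nz):
        sl = data[:, :, z]
        if not sl.any():
            raise ValueError(f"slice {z} is empty; violates mask invariants")
        com = ndimage.center_of_mass(sl)
        radii, flagged = _slice_radii(sl, com)
        if flagged:
            flags[z] = "center of mass outside mask; last-inside fallback"
        values[z] = radii * vx
    return RDProfile(values, subject_id=subject_id, qc_flags=flags)


def cross_sectional_areas(mask: CordMask, subject_id: str = "") -> CSAProfile:
    """Per-slice area: voxel count times in-plane voxel area (mm^2)."""
    return CSAProfile(mask.slice_areas_mm2(), subject_id=subject_id)


SEGMENT_NAMES = ("C2", "C3", "C4", "C5", "C6", "C7", "C8", "T1")


@dataclass
class VertebralLevelMap:
    """Slice intervals [start, stop) per vertebral level, superior -> inferior.

    Slice indices follow the package convention (0 = most inferior), so C2
    holds the highest indices.  ``segments_for`` returns the spinal segments
    a vertebral level overlies (Ck -> C(k+1)-C(k+2)).
    """

    intervals: dict[str, tuple[int, int]]
    L: int

    def __post_init__(self) -> None:
        stops = [self.intervals[lv] for lv in VERTEBRAL_LEVELS]
        covered = sorted(self.intervals.values())
        pos = 0
        for start, stop in covered:
            if start != pos:
                raise ValueError("level intervals must tile [0, L) without gaps")
            pos = stop
        if pos != self.L:
            raise ValueError("level intervals must cover [0, L)")
        # superior -> inferior ordering: C2 starts above C3, etc.
        for hi, lo in zip(VERTEBRAL_LEVELS, VERTEBRAL_LEVELS[1:]):
            if self.intervals[hi][0] < self.intervals[lo][1]:
                raise ValueError("levels must be ordered superior to inferior")
        del stops

    def slices(self, level: str) -> np.ndarray:
        start, stop = self.intervals[level]
        return np.arange(start, stop)

    def span_slices(self, level_hi: str, level_lo: str) -> np.ndarray:
        """All slices from vertebral ``level_hi`` down to ``level_lo``."""
        i_hi = VERTEBRAL_LEVELS.index(level_hi)
        i_lo = VERTEBRAL_LEVELS.index(level_lo)
        if i_hi > i_lo:
            i_hi, i_lo = i_lo, i_hi
        start = self.intervals[VERTEBRAL_LEVELS[i_lo]][0]
        stop = self.intervals[VERTEBRAL_LEVELS[i_hi]][1]
        return np.arange(start, stop)

    @staticmethod
    def segments_for(level: str) -> tuple[str, str]:
        """Spinal segments overlain by a vertebral level (Ck -> Ck+1, Ck+2)."""
        k = int(level[1:])
        if not 2 <= k <= 7:
            raise ValueError("vertebral level must be C2..C7")
        return SEGMENT_NAMES[k - 1], SEGMENT_NAMES[k]

    @staticmethod
    def segments_for_span(level_hi: str, level_lo: str) -> tuple[str, str]:
        """Segments overlain by a span of vertebral levels (C3-C6 -> C4-C7)."""
        k_hi = int(level_hi[1:])
        k_lo = int(level_lo[1:])
        if k_hi > k_lo:
            k_hi, k_lo = k_lo, k_hi
        return SEGMENT_NAMES[k_hi - 1], SEGMENT_NAMES[k_lo - 1]

    def to_dict(self) -> dict:
        return {
            "L": self.L,
            "slice_convention": "0 = most inferior",
            "intervals": {lv: list(iv) for lv, iv in self.intervals.items()},
            "spinal_segments": {
                lv: list(self.segments_for(lv)) for lv in VERTEBRAL_LEVELS
            },
        }


def label_levels(L: int, boundaries: list[float] | None = None) -> VertebralLevelMap:
    """Build the vertebral-level map from fractional boundaries.

    ``boundaries`` are the 5 interior fractions of the C2 -> C7/T1 span,
    measured from the superior end, strictly increasing in (0, 1).  The
    default splits the span into equal sixths.
    """
    if boundaries is None:
        boundaries = [k / 6.0 for k in range(1, 6)]
    boundaries = [float(b) for b in boundaries]
    if len(boundaries) != 5:
        raise ValueError("need 5 interior boundaries for 6 levels")
    if not all(0.0 < b < 1.0 for b in boundaries):
        raise ValueError("boundaries must lie in (0, 1)")
    if any(b2 <= b1 for b1, b2 in zip(boundaries, boundaries[1:])):
        raise ValueError("boundaries must be strictly increasing")

    fr = [0.0, *boundaries, 1.0]  # superior -> inferior fractions
    intervals = {}
    for i, level in enumerate(VERTEBRAL_LEVELS):
        start = int(round(L * (1.0 - fr[i + 1])))
        stop = int(round(L * (1.0 - fr[i])))
        intervals[level] = (start, stop)
    return VertebralLevelMap(intervals, L)
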