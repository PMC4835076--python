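"""Bias correction, cropping and resampling to the working resolution.

The cervical region is delimited by two operator-supplied landmarks (a
sidecar JSON in practice): the superior one at the top of the odontoid
process, the inferior one at the mid C7/T1 vertebral body.  The volume is
cropped to that inferior-superior interval (with an in-plane margin around
the image center) and resampled to 0.3 mm isotropic with cubic
interpolation.

Non-uniformity correction is a deliberately simple polynomial stand-in for
the external N3 tool: a low-order polynomial is fit to the log-intensity of
bright voxels and divided out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

from .core import CordVolume, AXIS_IS

__all__ = [
    "LandmarkPair",
    "correct_bias",
    "crop_and_resample",
    "WORKING_VOXEL_MM",
]

WORKING_VOXEL_MM = 0.3
DEFAULT_INPLANE_MARGIN_MM = 20.0


@dataclass(frozen=True)
class LandmarkPair:
    """Voxel coordinates delimiting the cervical cord along inferior-superior.

    ``superior`` must be strictly above ``inferior`` along axis 2.
    """

    superior: tuple[int, int, int]
    inferior: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.superior) != 3 or len(self.inferior) != 3:
            raise ValueError("landmarks must be 3-element voxel coordinates")
        if not self.superior[AXIS_IS] > self.inferior[AXIS_IS]:
            raise ValueError(
                "superior landmark must lie strictly above the inferior one "
                "along the inferior-superior axis"
            )

    @classmethod
    def from_json(cls, path) -> "LandmarkPair":
        with open(path) as fh:
            d = json.load(fh)
        return cls(superior=tuple(d["superior"]), inferior=tuple(d["inferior"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"superior": list(self.superior), "inferior": list(self.inferior)},
                fh, indent=2,
            )


def _poly_design(coords: np.ndarray, order: int) -> np.ndarray:
    """Trivariate polynomial design matrix up to total degree ``order``."""
    cols = []
    for px, py, pz in product(range(order + 1), repeat=3):
        if px + py + pz <= order:
            cols.append(coords[:, 0] ** px * coords[:, 1] ** py * coords[:, 2] ** pz)
    return np.column_stack(cols)


def correct_bias(vol: CordVolume, poly_order: int = 1) -> CordVolume:
    """Divide out a smooth polynomial fit to log-intensity of bright voxels.

    A stand-in for full non-uniformity correction: bright voxels (above 70%
    of the 99th intensity percentile, i.e. the brightest tissue class,
    which for T2-like cord data is the CSF sheath spanning the whole cord)
    drive a least-squares fit of log-intensity against a trivariate
    polynomial of total degree ``poly_order``; the exponentiated fit is
    divided out everywhere and the overall mean intensity is restored.

    With ``poly_order=0`` the correction is a pure global rescale (identity
    once the mean is restored).
    """
    if poly_order < 0:
        raise ValueError("poly_order must be >= 0")
    data = vol.data
    if not (data > 0).any():
        raise ValueError("cannot bias-correct an all-zero volume")

    thresh = 0.7 * np.quantile(data[data > 0], 0.99)
    fg = data > max(thresh, 0.0)
    idx = np.argwhere(fg)
    # normalized coordinates in [-1, 1] for conditioning
    norm = np.array(data.shape, dtype=float) - 1.0
    norm[norm == 0] = 1.0
    coords = 2.0 * idx / norm - 1.0

    design = _poly_design(coords, poly_order)
    logi = np.log(data[fg])
    coef, *_ = np.linalg.lstsq(design, logi, rcond=None)

    all_idx = np.argwhere(np.ones(data.shape, dtype=bool))
    all_coords = 2.0 * all_idx / norm - 1.0
    field = np.exp(_poly_design(all_coords, poly_order) @ coef).reshape(data.shape)

    corrected = data / field
    corrected *= data.mean() / corrected.mean()
    return CordVolume(corrected, vol.voxel_mm)


def crop_and_resample(
    vol: CordVolume,
    lm: LandmarkPair,
    target_voxel_mm: float = WORKING_VOXEL_MM,
    inplane_margin_mm: float = DEFAULT_INPLANE_MARGIN_MM,
    order: int = 3,
) -> CordVolume:
    """Crop to the landmark interval and resample to ``target_voxel_mm``.

    The output spans exactly the [inferior, superior] landmark slices along
    axis 2 and an ``inplane_margin_mm`` half-width around the image center
    in-plane.  Cubic interpolation (``order=3``) is exact on constants.
    Slice 0 of the output is the most inferior slice.
    """
    data = vol.data
    shape = data.shape
    for lmk in (lm.superior, lm.inferior):
        if any(not (0 <= lmk[a] < shape[a]) for a in range(3)):
            raise ValueError(f"landmark {lmk} outside the volume {shape}")

    z0 = lm.inferior[AXIS_IS]
    z1 = lm.superior[AXIS_IS]

    vx, vy, vz = vol.voxel_mm
    # in-plane crop window (voxel units) around the image center
    half_w = [inplane_margin_mm / v for v in (vx, vy)]
    ctr = [(shape[a] - 1) / 2.0 for a in (0, 1)]
    x_lo = max(0.0, ctr[0] - half_w[0])
    x_hi = min(shape[0] - 1.0, ctr[0] + half_w[0])
    y_lo = max(0.0, ctr[1] - half_w[1])
    y_hi = min(shape[1] - 1.0, ctr[1] + half_w[1])

    fx, fy, fz = vx / target_voxel_mm, vy / target_voxel_mm, vz / target_voxel_mm
    nx = int(round((x_hi - x_lo) * fx)) + 1
    ny = int(round((y_hi - y_lo) * fy)) + 1
    nz = int(round((z1 - z0 + 1) * fz))

    gx = x_lo + np.arange(nx) / fx
    gy = y_lo + np.arange(ny) / fy
    gz = z0 + np.arange(nz) / fz
    mesh = np.meshgrid(gx, gy, gz, indexing="ij")
    out = ndimage.map_coordinates(
        data, np.stack([m.ravel() for m in mesh]), order=order, mode="nearest"
    ).reshape(nx, ny, nz)
    return CordVolume(out, target_voxel_mm)
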