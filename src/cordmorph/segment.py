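"""Cord segmentation via a double-threshold region scheme.

This is a reconstruction of a double-threshold segmentation: the original
method's exact threshold definitions are not public, so the contract here
is the one implemented below, and any externally produced mask can be
swapped in through :func:`load_external_mask`.

On T2-like contrast the cord sits between the dark background and the
bright CSF sheath, so per axial slice the candidate region is an intensity
band between two thresholds: the low one placed fractionally (``t_low_q``)
between the window's background reference (5th percentile) and the cord
reference (median of a small patch at the propagated centerline estimate),
the high one fractionally (``t_high_q``) between the cord reference and the
CSF reference (95th percentile).  The connected component containing the
propagated seed is kept and its holes filled; the centerline estimate is
propagated slice-to-slice from each slice's mask center of mass.  All
references are intensity quantiles, so the segmentation is invariant to
intensity shifts and positive rescaling, and lowering ``t_low_q`` (or
raising ``t_high_q``) widens the band and can only grow the mask.
"""

from __future__ import annotations

import json

import numpy as np
from scipy import ndimage

from .core import CordVolume, CordMask

__all__ = ["segment_dtbm", "load_external_mask", "validate_mask"]

DEFAULT_T_LOW_Q = 0.5
DEFAULT_T_HIGH_Q = 0.5
DEFAULT_WINDOW_MM = 15.0
MAX_LOST_SLICE_FRACTION = 0.10
_PATCH_HALF_MM = 1.5


def _slice_band_component(sl, center, t_low_q, t_high_q, win_half, patch_half):
    """Band-threshold one slice; return (mask2d, new_center, flags)."""
    nx, ny = sl.shape
    ci = int(round(center[0]))
    cj = int(round(center[1]))
    i0, i1 = max(0, ci - win_half), min(nx, ci + win_half + 1)
    j0, j1 = max(0, cj - win_half), min(ny, cj + win_half + 1)
    win = sl[i0:i1, j0:j1]

    # reference intensities: background, cord (patch at the propagated
    # center), CSF; thresholds interpolate between them
    i_bg = np.quantile(win, 0.05)
    i_csf = np.quantile(win, 0.95)
    patch = sl[max(0, ci - patch_half):ci + patch_half + 1,
               max(0, cj - patch_half):cj + patch_half + 1]
    i_cord = np.median(patch)

    lo = i_bg + t_low_q * (i_cord - i_bg)
    hi = i_cord + t_high_q * (i_csf - i_cord)
    if not hi > lo:
        return None, center, {"reason": "no contrast in window"}

    band = (sl >= lo) & (sl <= hi)
    labels, _ = ndimage.label(band)
    lab = labels[np.clip(ci, 0, nx - 1), np.clip(cj, 0, ny - 1)]
    if lab == 0:
        # seed voxel fell outside the band; try its 8-neighbourhood
        neigh = labels[max(0, ci - 1):ci + 2, max(0, cj - 1):cj + 2]
        vals = neigh[neigh > 0]
        if vals.size == 0:
            return None, center, {"reason": "seed outside candidate band"}
        lab = np.bincount(vals).argmax()
    comp = ndimage.binary_fill_holes(labels == lab)
    com = ndimage.center_of_mass(comp)
    return comp, (com[0], com[1]), {}


def segment_dtbm(
    vol: CordVolume,
    seed_point: tuple[int, int, int],
    t_low_q: float = DEFAULT_T_LOW_Q,
    t_high_q: float = DEFAULT_T_HIGH_Q,
    window_mm: float = DEFAULT_WINDOW_MM,
) -> CordMask:
    """Segment the cord with the double-threshold band scheme.

    Parameters
    ----------
    vol:
        Preprocessed volume (0.3 mm working grid expected, any spacing
        accepted).
    seed_point:
        ``(i, j, k)`` voxel inside the cord; segmentation starts at slice
        ``k`` and propagates outward in both directions.
    t_low_q, t_high_q:
        Fractional positions of the two thresholds: ``t_low_q`` between the
        background and cord reference intensities, ``t_high_q`` between the
        cord and CSF references (both in (0, 1), default 0.5 = midpoint).
        Lowering ``t_low_q`` or raising ``t_high_q`` widens the band and
        can only grow the mask.

    Returns
    -------
    CordMask
        With a ``qc`` dict: per-slice flags, interpolated slices, window
        used.  Empty-slice results are filled from the nearest good slice
        and flagged; losing more than 10% of slices is a hard error.
    """
    if not (0.0 < t_low_q < 1.0 and 0.0 < t_high_q < 1.0):
        raise ValueError("t_low_q and t_high_q must lie in (0, 1)")
    data = vol.data
    nx, ny, nz = data.shape
    i, j, k = (int(v) for v in seed_point)
    if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
        raise ValueError(f"seed point {seed_point} outside volume {data.shape}")

    win_half = max(2, int(round(window_mm / (2.0 * vol.voxel_mm[0]))))
    patch_half = max(1, int(round(_PATCH_HALF_MM / vol.voxel_mm[0])))
    mask = np.zeros_like(data, dtype=bool)
    flags: dict[int, dict] = {}

    seed_sl, seed_center, f = _slice_band_component(
        data[:, :, k], (i, j), t_low_q, t_high_q, win_half, patch_half
    )
    if seed_sl is None:
        raise ValueError(f"segmentation failed at the seed slice {k}: {f['reason']}")
    mask[:, :, k] = seed_sl

    for direction in (+1, -1):
        center = seed_center
        for z in range(k + direction, nz if direction > 0 else -1, direction):
            sl, center_new, f = _slice_band_component(
                data[:, :, z], center, t_low_q, t_high_q, win_half, patch_half
            )
            if sl is None:
                flags[z] = f
            else:
                mask[:, :, z] = sl
                center = center_new

    lost = sorted(flags)
    if len(lost) > MAX_LOST_SLICE_FRACTION * nz:
        raise ValueError(
            f"segmentation lost {len(lost)}/{nz} slices "
            f"(> {MAX_LOST_SLICE_FRACTION:.0%}); first failure: "
            f"slice {lost[0]}: {flags[lost[0]]['reason']}"
        )
    # fill flagged slices from the nearest successfully segmented slice
    good = np.array([z for z in range(nz) if z not in flags])
    for z in lost:
        nearest = good[np.abs(good - z).argmin()]
        mask[:, :, z] = mask[:, :, nearest]
        flags[z]["interpolated_from"] = int(nearest)

    qc = {
        "flagged_slices": {int(z): f for z, f in flags.items()},
        "n_interpolated": len(lost),
        "window_mm": window_mm,
        "t_low_q": t_low_q,
        "t_high_q": t_high_q,
    }
    return CordMask(mask, vol.voxel_mm, qc=qc)


def validate_mask(mask: CordMask, fill: bool = False) -> tuple[CordMask, dict]:
    """Check per-slice mask invariants; optionally repair.

    Each nonempty axial slice must be a single connected component without
    holes.  With ``fill=True`` holes are filled and the largest component is
    kept (both logged); otherwise violations are only reported.

    Returns the (possibly repaired) mask and a QC report dict.
    """
    data = mask.data.copy()
    report: dict = {"slices": {}, "n_multi_component": 0, "n_with_holes": 0,
                    "n_empty": 0}
    nz = data.shape[2]
    for z in range(nz):
        sl = data[:, :, z]
        entry = {}
        if not sl.any():
            report["n_empty"] += 1
            entry["empty"] = True
            report["slices"][z] = entry
            continue
        labels, n_comp = ndimage.label(sl)
        if n_comp > 1:
            report["n_multi_component"] += 1
            entry["components"] = int(n_comp)
            if fill:
                sizes = np.bincount(labels.ravel())[1:]
                keep = sizes.argmax() + 1
                removed = int(sl.sum() - sizes.max())
                sl = labels == keep
                entry["removed_voxels"] = removed
        filled = ndimage.binary_fill_holes(sl)
        n_hole_vox = int(filled.sum() - sl.sum())
        if n_hole_vox:
            report["n_with_holes"] += 1
            entry["hole_voxels"] = n_hole_vox
            if fill:
                sl = filled
        if fill:
            data[:, :, z] = sl
        if entry:
            report["slices"][z] = entry
    out = CordMask(data, mask.voxel_mm, qc=dict(mask.qc))
    out.qc["validation"] = report
    return out, report


def load_external_mask(path, reference: CordVolume | None = None,
                       fill: bool = True) -> CordMask:
    """Ingest an externally produced (e.g. manually edited) cord mask.

    The mask grid must match ``reference`` when one is given.  Invariant
    violations (multi-component slices, holes) are repaired when
    ``fill=True`` with a per-slice log in ``mask.qc``.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0.5
    voxel = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    if reference is not None:
        if data.shape != reference.shape:
            raise ValueError(
                f"mask grid {data.shape} does not match reference "
                f"{reference.shape}"
            )
        voxel = reference.voxel_mm
    mask = CordMask(data, voxel)
    mask, _ = validate_mask(mask, fill=fill)
    return mask


def write_qc_report(mask: CordMask, path) -> None:
    with open(path, "w") as fh:
        json.dump(mask.qc, fh, indent=2, default=str)
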