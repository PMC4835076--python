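"""Shared fixtures and independent oracle helpers.

The heavyweight fixture is a session-scoped 18+18 synthetic cohort with a
20% anterior-posterior atrophy plateau, processed through the real
standardization + morphometry path; several statistics and acceptance
tests share it to stay inside the time budget.
"""

from __future__ import annotations

import numpy as np
import pytest

from cordmorph import (AtrophyField, CohortSpec, PhantomSpec,
                       cross_sectional_areas, make_cohort, make_phantom,
                       radial_distances, standardize_length, straighten)
from cordmorph.standardize import cohort_standard_length


# --------------------------------------------------------------------------
# oracle helpers (kept independent of the implementation paths they check)


def boundary_pixel_rd_oracle(slice_mask: np.ndarray, voxel_mm: float,
                             n_angles: int = 72):
    """Brute-force RD oracle: max distance over boundary pixels per 5° bin.

    Returns (radii_mm, valid) where ``valid`` marks bins that contained at
    least one boundary pixel.  Angle convention matches the package:
    0° = anterior (decreasing j), counterclockwise seen from superior
    (90° = increasing i).
    """
    from scipy import ndimage

    com = ndimage.center_of_mass(slice_mask)
    eroded = ndimage.binary_erosion(slice_mask)
    bi, bj = np.nonzero(slice_mask & ~eroded)
    di = bi - com[0]
    dj = bj - com[1]
    # theta with sin(theta)=di/r, -cos(theta)=dj/r
    theta = np.rad2deg(np.arctan2(di, -dj)) % 360.0
    dist = np.hypot(di, dj) * voxel_mm
    # nearest angular bin: pixels within +/- 2.5 deg of each ray
    bins = np.round(theta / (360.0 / n_angles)).astype(int) % n_angles
    radii = np.zeros(n_angles)
    valid = np.zeros(n_angles, dtype=bool)
    for b, d in zip(bins, dist):
        valid[b] = True
        radii[b] = max(radii[b], d)
    return radii, valid


def exact_two_group_pvalues(ctl: np.ndarray, pat: np.ndarray) -> np.ndarray:
    """Enumerate all relabelings of a small two-group comparison.

    One-sided p of T = mean(ctl) - mean(pat) per column, by exhausting all
    C(n, n_ctl) relabelings (the identity included).
    """
    from itertools import combinations

    X = np.vstack([ctl, pat])
    n = X.shape[0]
    n_c = ctl.shape[0]
    t_obs = ctl.mean(axis=0) - pat.mean(axis=0)
    count = np.zeros(X.shape[1])
    total = 0
    for comb in combinations(range(n), n_c):
        sel = np.zeros(n, dtype=bool)
        sel[list(comb)] = True
        t = X[sel].mean(axis=0) - X[~sel].mean(axis=0)
        count += t >= t_obs - 1e-12
        total += 1
    return count / total


def rasterize_convex_polygon(vertices: np.ndarray, shape: tuple[int, int]):
    """Voxel-center inclusion mask of a convex polygon via half-plane tests."""
    ii, jj = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    inside = np.ones(shape, dtype=bool)
    n = len(vertices)
    # vertices assumed counterclockwise
    for a in range(n):
        p, q = vertices[a], vertices[(a + 1) % n]
        cross = (q[0] - p[0]) * (jj - p[1]) - (q[1] - p[1]) * (ii - p[0])
        inside &= cross >= 0
    return inside


def random_convex_polygon(rng, center, radius_range, n_pts=9):
    """Convex hull of random points around ``center`` (ccw vertex order)."""
    from scipy.spatial import ConvexHull

    ang = np.sort(rng.uniform(0, 2 * np.pi, n_pts))
    rad = rng.uniform(*radius_range, n_pts)
    pts = np.column_stack([center[0] + rad * np.cos(ang),
                           center[1] + rad * np.sin(ang)])
    hull = ConvexHull(pts)
    return pts[hull.vertices]


# --------------------------------------------------------------------------
# fixtures


ATROPHY_SPAN = (1.0 / 6.0, 5.0 / 6.0)  # the C3-C6 vertebral span, inferior-origin


def _small_phantom_spec(**kw) -> PhantomSpec:
    defaults = dict(voxel_mm=0.3, cord_length_mm=40.0, fov_mm=30.0, seed=7)
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture()
def small_spec() -> PhantomSpec:
    return _small_phantom_spec()


@pytest.fixture()
def circle_mask():
    """Straight circular tube, r = 4 mm, 0.3 mm voxels."""
    spec = PhantomSpec(voxel_mm=0.3, cord_length_mm=6.0, fov_mm=20.0,
                       ap_semiaxis_mm=[(0.0, 4.0), (1.0, 4.0)],
                       rl_semiaxis_mm=[(0.0, 4.0), (1.0, 4.0)], seed=0)
    _, mask, truth = make_phantom(spec, render_volume=False)
    return mask, truth


@pytest.fixture(scope="session")
def cohort18():
    """18+18 masks-only cohort with a 20% A-P atrophy plateau over 'C3-C6'.

    Returns a dict with standardized CSA/RD profiles per group, the level
    map length L, the atrophy field and the subject records.
    """
    atrophy = AtrophyField(direction="anterior-posterior", peak=0.20,
                           extent=ATROPHY_SPAN, transition=0.06)
    cspec = CohortSpec(n_patients=18, n_controls=18, atrophy=atrophy,
                       between_subject_cv=0.05, clinical_coupling=0.0, seed=11)
    pspec = PhantomSpec(voxel_mm=0.3, cord_length_mm=123.9, fov_mm=40.0, seed=11)
    cohort = make_cohort(cspec, pspec, render_volumes=False)

    L = cohort_standard_length([s.mask for s in cohort.subjects])
    out = {"L": L, "atrophy": atrophy, "cohort": cohort,
           "csa": {"patient": [], "control": []},
           "rd": {"patient": [], "control": []},
           "records": cohort.records()}
    for sub in cohort.subjects:
        straight, _ = straighten(sub.mask)
        std = standardize_length(straight, L)
        out["csa"][sub.group].append(cross_sectional_areas(std, sub.id))
        out["rd"][sub.group].append(radial_distances(std, sub.id))
    return out
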