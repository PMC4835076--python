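"""Synthetic cervical-cord phantoms and cohorts with known ground truth.

The phantom is a curved elliptical tube (the cord) wrapped in a brighter
sheath (CSF, T2-like contrast) on a dark background.  Per-slice ellipse
semi-axes follow a cervical-enlargement profile, a configurable atrophy
field shrinks the patient cords, and a cohort generator attaches clinical
scores with configurable coupling to the injected atrophy.

Every generated object carries its analytic ground truth (semi-axes,
cross-sectional area, centerline) so downstream modules can be validated
against known geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .core import CordVolume, CordMask

__all__ = [
    "PhantomSpec",
    "AtrophyField",
    "CohortSpec",
    "GroundTruth",
    "Subject",
    "Cohort",
    "make_phantom",
    "make_cohort",
]

# Cervical-enlargement default semi-axis profiles (fraction of cord length
# measured from the inferior end -> semi-axis in mm).  CSA rises from
# ~60 mm^2 at C7/T1 through a maximum ~87 mm^2 near C4-C5 and falls back
# to ~70 mm^2 at C2.  Absolute values are configuration, not facts.
DEFAULT_AP_SEMIAXIS = ((0.0, 3.2), (0.5, 4.0), (0.65, 4.0), (1.0, 3.4))
DEFAULT_RL_SEMIAXIS = ((0.0, 6.0), (0.5, 6.9), (0.65, 6.9), (1.0, 6.5))


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise parameters of a single phantom.

    ``voxel_mm`` defaults to the acquisition resolution (0.9 mm); set it to
    0.3 to generate directly on the working grid.
    """

    cord_length_mm: float = 123.9
    voxel_mm: float = 0.9
    n_slices_acq: int | None = None
    fov_mm: float = 40.0
    centerline_amplitude_mm: float = 0.0
    ap_semiaxis_mm: Sequence[tuple[float, float]] = DEFAULT_AP_SEMIAXIS
    rl_semiaxis_mm: Sequence[tuple[float, float]] = DEFAULT_RL_SEMIAXIS
    csf_ring_mm: float = 1.5
    cord_intensity: float = 120.0
    csf_intensity: float = 230.0
    background_intensity: float = 10.0
    noise_sigma: float = 0.0
    bias_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices_acq is None:
            self.n_slices_acq = int(round(self.cord_length_mm / self.voxel_mm))
        for name in ("ap_semiaxis_mm", "rl_semiaxis_mm"):
            pts = tuple((float(f), float(v)) for f, v in getattr(self, name))
            if any(v <= 0 for _, v in pts):
                raise ValueError(f"{name} must be > 0 everywhere")
            fr = [f for f, _ in pts]
            if fr != sorted(fr):
                raise ValueError(f"{name} control fractions must be increasing")
            setattr(self, name, pts)
        if self.csf_intensity <= self.cord_intensity:
            raise ValueError("CSF must be brighter than cord (T2-like contrast)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.voxel_mm <= 0 or self.cord_length_mm <= 0 or self.fov_mm <= 0:
            raise ValueError("sizes must be > 0")

    def semiaxes_at(self, z_frac: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interpolate (A-P, R-L) semi-axes at fractional cord positions."""
        ap = np.interp(z_frac, *zip(*self.ap_semiaxis_mm))
        rl = np.interp(z_frac, *zip(*self.rl_semiaxis_mm))
        return ap, rl

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        return cls(**json.loads(text))


AtrophyDirection = Literal["anterior-posterior", "right-left", "isotropic", "anterior"]


@dataclass
class AtrophyField:
    """Per-slice fractional reduction applied to patient cords.

    ``extent`` is the (inferior, superior) span as fractions of cord length;
    inside it the reduction ramps up to ``peak`` over ``transition`` (also a
    length fraction) with a smoothstep profile and is zero outside.

    Directions:

    * ``anterior-posterior`` — scales the A-P semi-axis (area loss == profile)
    * ``right-left`` — scales the R-L semi-axis
    * ``isotropic`` — scales the area (each axis by sqrt(1-profile))
    * ``anterior`` — flattens only the anterior half of the ellipse, which
      displaces the section's center of mass posteriorly (area loss ==
      profile/2)
    """

    direction: AtrophyDirection = "anterior-posterior"
    peak: float = 0.2
    extent: tuple[float, float] = (1.0 / 6.0, 5.0 / 6.0)
    transition: float = 0.06

    def __post_init__(self) -> None:
        if not (0.0 <= self.peak < 1.0):
            raise ValueError("peak must be in [0, 1)")
        lo, hi = self.extent
        if hi < lo:
            raise ValueError("extent must be (inferior, superior) with lo <= hi")
        if self.direction not in (
            "anterior-posterior",
            "right-left",
            "isotropic",
            "anterior",
        ):
            raise ValueError(f"unknown atrophy direction {self.direction!r}")

    @property
    def is_empty(self) -> bool:
        lo, hi = self.extent
        return self.peak == 0.0 or hi <= lo

    def profile(self, z_frac: np.ndarray) -> np.ndarray:
        """Fractional reduction at fractional cord positions, in [0, 1)."""
        z = np.asarray(z_frac, dtype=float)
        if self.is_empty:
            return np.zeros_like(z)
        lo, hi = self.extent
        w = min(self.transition, (hi - lo) / 2.0)
        out = np.zeros_like(z)
        inside = (z >= lo) & (z <= hi)
        if w <= 0:
            out[inside] = self.peak
            return out
        # smoothstep ramps just inside each end of the extent
        t_lo = np.clip((z - lo) / w, 0.0, 1.0)
        t_hi = np.clip((hi - z) / w, 0.0, 1.0)
        ramp = np.minimum(t_lo, t_hi)
        ramp = ramp * ramp * (3.0 - 2.0 * ramp)
        out[inside] = self.peak * ramp[inside]
        return out

    def scaled(self, peak: float) -> "AtrophyField":
        return AtrophyField(self.direction, peak, self.extent, self.transition)


@dataclass
class GroundTruth:
    """Analytic per-slice truth for one phantom."""

    ap_mm: np.ndarray          # effective A-P semi-axis after atrophy
    rl_mm: np.ndarray          # effective R-L semi-axis after atrophy
    csa_mm2: np.ndarray        # true cross-sectional area
    center_mm: np.ndarray      # (n_slices, 2) in-plane centerline, mm
    atrophy_profile: np.ndarray
    bias_field: np.ndarray | None = None


def _ellipse_mask_2d(xx, yy, xc, yc, a_ap, b_rl, anterior_scale=1.0):
    """Voxel-center inclusion test; ``anterior_scale`` shrinks y < yc half."""
    dy = yy - yc
    a_eff = np.where(dy < 0, a_ap * anterior_scale, a_ap)
    return (xx - xc) ** 2 / b_rl**2 + dy**2 / a_eff**2 <= 1.0


def make_phantom(
    spec: PhantomSpec,
    atrophy: AtrophyField | None = None,
    render_volume: bool = True,
) -> tuple[CordVolume | None, CordMask, GroundTruth]:
    """Generate one phantom volume/mask pair with its analytic ground truth.

    The mask is the noise-free truth (voxel centers inside the ellipse).
    The volume adds the CSF sheath, multiplicative bias and Gaussian noise.
    Set ``render_volume=False`` to skip intensity rendering when only the
    mask is needed (mask-only pipelines, large cohorts).

    Raises
    ------
    ValueError
        If the sheathed ellipse does not fit inside the in-plane FOV.
    """
    rng = np.random.default_rng(spec.seed)
    nz = spec.n_slices_acq
    nxy = int(round(spec.fov_mm / spec.voxel_mm))
    z_frac = np.arange(nz) / max(nz - 1, 1)

    ap, rl = spec.semiaxes_at(z_frac)
    prof = atrophy.profile(z_frac) if atrophy is not None else np.zeros(nz)
    anterior_scale = np.ones(nz)
    if atrophy is not None and not atrophy.is_empty:
        if atrophy.direction == "anterior-posterior":
            ap = ap * (1.0 - prof)
        elif atrophy.direction == "right-left":
            rl = rl * (1.0 - prof)
        elif atrophy.direction == "isotropic":
            s = np.sqrt(1.0 - prof)
            ap, rl = ap * s, rl * s
        else:  # anterior-only flattening
            anterior_scale = 1.0 - prof

    csa = np.pi * ap * rl * (1.0 + anterior_scale) / 2.0

    half_fov = spec.fov_mm / 2.0
    # in-plane voxel-center coordinates, grid centered on 0
    coords = (np.arange(nxy) - (nxy - 1) / 2.0) * spec.voxel_mm
    xx, yy = np.meshgrid(coords, coords, indexing="ij")

    xc = np.zeros(nz)
    yc = -spec.centerline_amplitude_mm * np.sin(np.pi * z_frac)  # A-P bow

    reach = np.maximum(np.abs(yc) + ap + spec.csf_ring_mm, rl + spec.csf_ring_mm)
    if (reach >= half_fov).any():
        raise ValueError(
            f"cord + CSF sheath (max reach {reach.max():.1f} mm) exceeds the "
            f"{spec.fov_mm:.1f} mm field of view; enlarge fov_mm"
        )

    mask = np.zeros((nxy, nxy, nz), dtype=bool)
    vol = None
    if render_volume:
        vol = np.full((nxy, nxy, nz), spec.background_intensity, dtype=np.float64)
    for k in range(nz):
        inside = _ellipse_mask_2d(xx, yy, xc[k], yc[k], ap[k], rl[k], anterior_scale[k])
        mask[:, :, k] = inside
        if render_volume:
            sheath = _ellipse_mask_2d(
                xx, yy, xc[k], yc[k],
                ap[k] + spec.csf_ring_mm, rl[k] + spec.csf_ring_mm,
                anterior_scale[k],
            )
            vol[sheath, k] = spec.csf_intensity
            vol[inside, k] = spec.cord_intensity

    bias = None
    if render_volume:
        if spec.bias_amplitude != 0.0:
            bias = _bias_field((nxy, nxy, nz), spec.bias_amplitude, rng)
            vol *= bias
        else:
            rng.random(3)  # keep the stream aligned whether or not bias is on
        if spec.noise_sigma > 0:
            vol += rng.normal(0.0, spec.noise_sigma, size=vol.shape)

    truth = GroundTruth(
        ap_mm=ap, rl_mm=rl, csa_mm2=csa,
        center_mm=np.column_stack([xc, yc]),
        atrophy_profile=prof, bias_field=bias,
    )
    volume = CordVolume(vol, spec.voxel_mm) if render_volume else None
    return volume, CordMask(mask, spec.voxel_mm), truth


def _bias_field(shape, amplitude, rng) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * (w . x), |field-1| <= amp."""
    w = rng.standard_normal(3)
    w /= np.linalg.norm(w)
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    g = w[0] * gx + w[1] * gy + w[2] * gz
    g /= max(np.abs(g).max(), 1e-12)
    return 1.0 + amplitude * g


# ---------------------------------------------------------------------------
# cohorts

# Table-1-like clinical marginals used as generator defaults: (mean, sd) on
# the percent-of-maximum scale for MMT, raw scale otherwise.
DEFAULT_CLINICAL = {
    "mmt_pct_c5": (73.3, 19.4),
    "mmt_pct_c6": (84.4, 18.9),
    "mmt_pct_c7": (86.9, 15.2),
    "mmt_pct_c8": (72.2, 13.5),
    "mmt_leg": (46.7, 15.2),
    "mfm_d1": (19.5, 11.1),
    "mfm_d2": (37.4, 1.6),
    "mfm_d3": (38.3, 1.5),
    "alsfrs_arm": (7.1, 1.2),
    "alsfrs_leg": (3.3, 1.4),
    "alsfrs_total": (40.2, 3.8),
    "disease_duration_years": (26.0, 15.0),
    "age": (36.0, 11.0),
}

MMT_LEVEL_MAX = {"c5": 10, "c6": 10, "c7": 30, "c8": 20}


@dataclass
class CohortSpec:
    """Two-group cohort: sizes, atrophy field, variability and coupling."""

    n_patients: int = 18
    n_controls: int = 18
    atrophy: AtrophyField = field(default_factory=AtrophyField)
    between_subject_cv: float = 0.05
    clinical_coupling: float = 0.0
    clinical_marginals: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("group sizes must be >= 2")
        if not (-1.0 <= self.clinical_coupling <= 1.0):
            raise ValueError("clinical_coupling must be in [-1, 1]")
        if self.between_subject_cv < 0:
            raise ValueError("between_subject_cv must be >= 0")


@dataclass
class Subject:
    id: str
    group: str  # "patient" | "control"
    volume: CordVolume | None
    mask: CordMask
    truth: GroundTruth
    record: dict


@dataclass
class Cohort:
    subjects: list[Subject]
    spec: CohortSpec
    phantom_spec: PhantomSpec

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def patients(self) -> list[Subject]:
        return [s for s in self.subjects if s.group == "patient"]

    @property
    def controls(self) -> list[Subject]:
        return [s for s in self.subjects if s.group == "control"]

    def records(self) -> list[dict]:
        return [dict(s.record, id=s.id, group=s.group) for s in self.subjects]


def _truncnorm_pct(latent: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Map standard-normal latents to a truncated-normal percent scale.

    Strictly monotone in the latent, so rank correlations injected through
    the latent survive exactly (no clipping ties).
    """
    a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
    u = sps.norm.cdf(latent)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return sps.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def make_cohort(
    cspec: CohortSpec,
    spec: PhantomSpec,
    render_volumes: bool = True,
) -> Cohort:
    """Generate a patient/control cohort of phantoms plus clinical records.

    Patients carry ``cspec.atrophy`` with the subject-level peak jittered by
    ``between_subject_cv``; controls carry none.  Baseline semi-axes are
    jittered per subject and axis by the same CV.  MMT percent scores are
    drawn from truncated-normal marginals through a Gaussian copula whose
    correlation with the subject's peak atrophy is ``clinical_coupling``
    (controls get no clinical scores, as in a healthy-volunteer arm).
    """
    rng = np.random.default_rng(cspec.seed)
    subjects: list[Subject] = []
    n_total = cspec.n_patients + cspec.n_controls

    groups = ["patient"] * cspec.n_patients + ["control"] * cspec.n_controls
    axis_jitter = 1.0 + cspec.between_subject_cv * rng.standard_normal((n_total, 2))
    axis_jitter = np.clip(axis_jitter, 0.5, 1.5)
    peak_jitter = 1.0 + cspec.between_subject_cv * rng.standard_normal(n_total)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_total)

    peaks = np.zeros(n_total)
    for idx, group in enumerate(groups):
        if group == "patient" and not cspec.atrophy.is_empty:
            peaks[idx] = float(
                np.clip(cspec.atrophy.peak * peak_jitter[idx], 0.0, 0.95)
            )

    for idx, group in enumerate(groups):
        sub_spec = PhantomSpec(
            cord_length_mm=spec.cord_length_mm,
            voxel_mm=spec.voxel_mm,
            n_slices_acq=spec.n_slices_acq,
            fov_mm=spec.fov_mm,
            centerline_amplitude_mm=spec.centerline_amplitude_mm,
            ap_semiaxis_mm=[(f, v * axis_jitter[idx, 0]) for f, v in spec.ap_semiaxis_mm],
            rl_semiaxis_mm=[(f, v * axis_jitter[idx, 1]) for f, v in spec.rl_semiaxis_mm],
            csf_ring_mm=spec.csf_ring_mm,
            cord_intensity=spec.cord_intensity,
            csf_intensity=spec.csf_intensity,
            background_intensity=spec.background_intensity,
            noise_sigma=spec.noise_sigma,
            bias_amplitude=spec.bias_amplitude,
            seed=int(sub_seeds[idx]),
        )
        atro = cspec.atrophy.scaled(peaks[idx]) if peaks[idx] > 0 else None
        volume, mask, truth = make_phantom(sub_spec, atro, render_volume=render_volumes)
        sid = f"sub-{idx + 1:02d}"
        subjects.append(Subject(sid, group, volume, mask, truth, {}))

    # clinical scores (patients only): Gaussian copula against peak atrophy
    pat_idx = [i for i, g in enumerate(groups) if g == "patient"]
    pk = peaks[pat_idx]
    z_atr = (pk - pk.mean()) / pk.std() if pk.std() > 0 else np.zeros(len(pk))
    c = cspec.clinical_coupling
    marg = cspec.clinical_marginals

    for j, idx in enumerate(pat_idx):
        rec: dict = {}
        noise = rng.standard_normal(4)
        for li, lvl in enumerate(("c5", "c6", "c7", "c8")):
            latent = c * z_atr[j] + np.sqrt(max(0.0, 1.0 - c**2)) * noise[li]
            mean, sd = marg[f"mmt_pct_{lvl}"]
            pct = float(_truncnorm_pct(np.array([latent]), mean, sd)[0])
            raw = int(round(pct * MMT_LEVEL_MAX[lvl] / 100.0))
            rec[f"mmt_pct_{lvl}"] = pct
            rec[f"mmt_{lvl}"] = raw
        rec["mmt_arm"] = sum(rec[f"mmt_{l}"] for l in ("c5", "c6", "c7", "c8"))
        for name in (
            "mmt_leg", "mfm_d1", "mfm_d2", "mfm_d3",
            "alsfrs_arm", "alsfrs_leg", "alsfrs_total",
            "disease_duration_years",
        ):
            mean, sd = marg[name]
            rec[name] = float(np.clip(rng.normal(mean, sd), 0.0, None))
        rec["mmt_leg"] = int(round(np.clip(rec["mmt_leg"], 0, 70)))
        rec["mmt_total"] = rec["mmt_arm"] + rec["mmt_leg"]
        for name, hi in (("mfm_d1", 39), ("mfm_d2", 39), ("mfm_d3", 39),
                         ("alsfrs_arm", 8), ("alsfrs_leg", 8), ("alsfrs_total", 48)):
            rec[name] = float(min(rec[name], hi))
        rec["peak_atrophy"] = float(pk[j])
        subjects[idx].record.update(rec)

    mean_age, sd_age = marg["age"]
    for idx, sub in enumerate(subjects):
        sub.record.setdefault("peak_atrophy", 0.0)
        sub.record["age"] = float(np.clip(rng.normal(mean_age, sd_age), 18.0, 90.0))
        sub.record["sex"] = "M" if rng.random() < 0.5 else "F"

    return Cohort(subjects, cspec, spec)
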