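"""End-to-end pipeline driver: cohort directory in, result bundle out.

A cohort directory contains ``subjects.csv`` (``id``, ``group`` and any
clinical columns) plus per-subject files named ``{id}_vol.nii``,
``{id}_mask.nii`` and ``{id}_landmarks.json``.  Stages run in order
preprocess -> segment (or external masks) -> standardize -> morphometry ->
stats; all outputs land under ``config.out_dir`` with a provenance record.
Any stage failure aborts with the stage name and subject id.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import CordMask
from .io import RunConfig, read_mask, read_volume, write_matrix_csv, write_nifti
from .morphometry import (cross_sectional_areas, label_levels,
                          radial_distances)
from .phantom import Cohort
from .preprocess import LandmarkPair, correct_bias, crop_and_resample
from .segment import load_external_mask, segment_dtbm, validate_mask
from .standardize import cohort_standard_length, standardize_length, straighten
from .stats import (atrophy_rate, correlate_profiles, gradient_correlation,
                    permutation_map, proximal_distal_test, table1_summary)

__all__ = ["run_pipeline", "write_cohort", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, subject: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed for subject '{subject}': {cause}")
        self.stage = stage
        self.subject = subject


def write_cohort(cohort: Cohort, out_dir, config_hash: str = "",
                 write_volumes: bool = True) -> Path:
    """Materialize a synthetic cohort as a pipeline-ready directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in cohort.subjects:
        if write_volumes and sub.volume is not None:
            write_nifti(sub.volume, out / f"{sub.id}_vol.nii", config_hash)
            nz = sub.volume.n_slices
            ctr = [s // 2 for s in sub.volume.shape[:2]]
            LandmarkPair(superior=(ctr[0], ctr[1], nz - 1),
                         inferior=(ctr[0], ctr[1], 0)).to_json(
                out / f"{sub.id}_landmarks.json")
        write_nifti(sub.mask, out / f"{sub.id}_mask.nii", config_hash)
        truth = pd.DataFrame({
            "ap_mm": sub.truth.ap_mm,
            "rl_mm": sub.truth.rl_mm,
            "csa_mm2": sub.truth.csa_mm2,
            "atrophy": sub.truth.atrophy_profile,
        })
        truth.to_csv(out / f"{sub.id}_truth.csv", index_label="slice")
        rows.append(dict(sub.record, id=sub.id, group=sub.group))
    pd.DataFrame(rows).to_csv(out / "subjects.csv", index=False)
    return out


def _subject_mask(sid: str, cfg: RunConfig, cohort: Path) -> CordMask:
    masks_dir = Path(cfg.masks_dir) if cfg.masks_dir else cohort
    if cfg.skip_segmentation:
        return load_external_mask(masks_dir / f"{sid}_mask.nii")
    vol = read_volume(cohort / f"{sid}_vol.nii")
    if cfg.bias_poly_order > 0:
        vol = correct_bias(vol, cfg.bias_poly_order)
    lm_path = cohort / f"{sid}_landmarks.json"
    if lm_path.exists():
        lm = LandmarkPair.from_json(lm_path)
        vol = crop_and_resample(vol, lm, cfg.target_voxel_mm)
    seed_point = (vol.shape[0] // 2, vol.shape[1] // 2, vol.shape[2] // 2)
    mask = segment_dtbm(vol, seed_point, cfg.t_low_q, cfg.t_high_q)
    mask, _ = validate_mask(mask, fill=True)
    return mask


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis described by ``config``; returns a result dict."""
    cohort = Path(config.cohort_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    subjects = pd.read_csv(cohort / "subjects.csv")
    if "id" not in subjects or "group" not in subjects:
        raise ValueError("subjects.csv must have 'id' and 'group' columns")

    masks: dict[str, CordMask] = {}
    for sid in subjects["id"]:
        try:
            masks[sid] = _subject_mask(sid, config, cohort)
        except Exception as exc:  # noqa: BLE001 - abort naming stage+subject
            raise PipelineError("segment" if not config.skip_segmentation
                                else "load_mask", sid, exc) from exc

    straightened = {}
    for sid, mask in masks.items():
        try:
            straightened[sid], _ = straighten(mask)
        except Exception as exc:
            raise PipelineError("straighten", sid, exc) from exc

    L = config.standard_length or cohort_standard_length(list(straightened.values()))
    rd, csa = {}, {}
    for sid, mask in straightened.items():
        try:
            std = standardize_length(mask, L)
            rd[sid] = radial_distances(std, subject_id=sid)
            csa[sid] = cross_sectional_areas(std, subject_id=sid)
        except Exception as exc:
            raise PipelineError("morphometry", sid, exc) from exc
        write_matrix_csv(rd[sid].values, out / f"{sid}_rd.csv", chash,
                         columns=[f"{a:g}deg" for a in rd[sid].angles_deg],
                         extra_comments=("radial distance (mm); 0deg=anterior, ccw from superior",))
        write_matrix_csv(csa[sid].values, out / f"{sid}_csa.csv", chash,
                         extra_comments=("cross-sectional area (mm^2)",))

    levels = label_levels(L, config.level_boundaries)
    with open(out / "level_map.json", "w") as fh:
        json.dump(dict(levels.to_dict(), config_hash=chash), fh, indent=2)

    pat_ids = list(subjects.loc[subjects.group == "patient", "id"])
    ctl_ids = list(subjects.loc[subjects.group == "control", "id"])
    results: dict = {"L": L, "config_hash": chash, "n_patients": len(pat_ids),
                     "n_controls": len(ctl_ids)}

    if pat_ids and ctl_ids:
        csa_map = permutation_map([csa[s] for s in pat_ids],
                                  [csa[s] for s in ctl_ids],
                                  n_perm=config.n_perm, alpha=config.alpha,
                                  seed=config.seed, side=config.side)
        rd_map = permutation_map([rd[s] for s in pat_ids],
                                 [rd[s] for s in ctl_ids],
                                 n_perm=config.n_perm, alpha=config.alpha,
                                 seed=config.seed + 1, side=config.side)
        rate = atrophy_rate([csa[s] for s in pat_ids], [csa[s] for s in ctl_ids])
        write_matrix_csv(csa_map.p_values, out / "csa_pvalues.csv", chash)
        write_matrix_csv(rd_map.p_values, out / "rd_pvalues.csv", chash)
        write_matrix_csv(rate.rate_pct, out / "atrophy_rate_pct.csv", chash)
        results["csa_map"] = csa_map
        results["rd_map"] = rd_map
        results["atrophy_rate"] = rate
        results["atrophy_range_significant"] = rate.significant_range(csa_map)

        pat_df = subjects.set_index("id").loc[pat_ids]
        clin_cols = [c for c in pat_df.columns
                     if c.startswith(("mmt_pct_", "mfm_", "alsfrs_"))
                     or c == "disease_duration_years"]
        corr = {}
        for col in clin_cols:
            scores = pd.to_numeric(pat_df[col], errors="coerce").to_numpy()
            if np.isfinite(scores).sum() >= 4:
                cmap = correlate_profiles([csa[s] for s in pat_ids], scores,
                                          alpha=config.alpha)
                corr[col] = cmap
                write_matrix_csv(cmap.p_values, out / f"corr_csa_{col}_pvalues.csv", chash)
        results["correlations"] = corr

        mmt_cols = ["mmt_pct_c5", "mmt_pct_c6", "mmt_pct_c7", "mmt_pct_c8"]
        if len(pat_ids) >= 4 and all(c in pat_df for c in mmt_cols):
            mmt = pat_df[mmt_cols].to_numpy(dtype=float)
            if np.isfinite(mmt).all():
                results["gradient_correlation"] = gradient_correlation(
                    [csa[s] for s in pat_ids], levels, mmt,
                    voxel_mm_z=config.target_voxel_mm)
                results["proximal_distal"] = proximal_distal_test(
                    mmt[:, 0], mmt[:, 3])

    table = table1_summary(subjects.to_dict("records"))
    table.to_csv(out / "table1.csv", index=False)
    results["table1"] = table

    provenance = {
        "package": "cordmorph",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": chash,
        "standard_length": L,
        "subjects": sorted(masks),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return results
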