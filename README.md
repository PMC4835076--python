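# cordmorph

Surface-based morphometry of the cervical spinal cord: synthetic cord
phantoms with known ground truth, double-threshold cord segmentation,
straightening and length standardization, radial-distance (RD) and
cross-sectional-area (CSA) profiling, and permutation-based group atrophy
mapping with clinical-score statistics.

## What it does

The pipeline processes T2-like volumes (NIfTI) with binary cord masks:

1. **phantom** — generates single subjects and whole cohorts of curved
   elliptical cord phantoms (CSF sheath, bias field, noise), with
   configurable atrophy fields and clinical scores whose coupling to
   atrophy is controllable (default: none).  Every phantom carries its
   analytic per-slice semi-axes and CSA.
2. **preprocess** — optional polynomial bias correction, cropping to two
   operator landmarks and cubic resampling to a 0.3 mm working grid.
3. **segment** — a double-threshold band segmentation (a reconstruction;
   external/manually edited masks can be swapped in and are validated
   against the mask invariants).
4. **standardize** — per-slice integer-voxel straightening (area
   preserving) and nearest-neighbour rescaling to a common slice count
   (default 413; cohort median available).
5. **morphometry** — RD: 72 radii per slice (one per 5°, 0° = anterior,
   counterclockwise from superior) from the slice center of mass with
   sub-voxel border localization; CSA: voxel count × 0.09 mm²; vertebral
   level map C2–C7 with the vertebral→spinal segment lookup.
6. **stats** — one-sided permutation maps (default 100,000 permutations,
   add-one p estimator, supra-significance α = 10⁻³), atrophy-rate
   profiles, site-wise Spearman correlation maps (exact permutation null
   for n ≤ 10), CSA-gradient vs MMT-gradient slope correlation, paired
   Wilcoxon proximal/distal test and cohort summary tables.

Axis convention everywhere: array axes (R–L, A–P, I–S), slice 0 is the
most inferior slice, 0-based voxel indices.

## CLI

```sh
# synthetic 18+18 cohort with a 20% anterior-posterior atrophy plateau
cordmorph simulate --out-dir cohort/ --atrophy-peak 0.2 --noise-sigma 5 --seed 1

# full analysis (preprocess -> segment -> standardize -> measure -> stats)
cordmorph run-all --cohort-dir cohort/ --out-dir out/ --n-perm 100000 --seed 1

# from externally produced masks instead of running the segmenter
cordmorph run-all --cohort-dir cohort/ --out-dir out/ --skip-segmentation \
    --masks-dir cohort/

# individual stages
cordmorph preprocess vol.nii landmarks.json --out pre.nii
cordmorph segment pre.nii --out mask.nii --qc-report qc.json
cordmorph standardize mask.nii --out std.nii -L 413
cordmorph measure std.nii --rd-out rd.csv --csa-out csa.csv
cordmorph compare --patients p1.csv --patients p2.csv \
    --controls c1.csv --controls c2.csv --p-out p.csv --rate-out rate.csv
```

Outputs are CSV (profiles, p-value maps, atrophy rate, summary tables),
JSON (config, QC, level map, provenance) and uncompressed NIfTI; every
CSV/JSON embeds the run-config hash, and reruns with an identical
configuration are byte-identical.

## Notes

- The segmentation is a declared reconstruction: the band thresholds are
  placed fractionally between background/cord and cord/CSF reference
  intensities taken from a 15×15 mm window around the propagated
  centerline, making it invariant to intensity shifts and positive
  rescaling. Any other segmenter can be used via `load_external_mask`.
- No multiple-testing correction is applied beyond the stringent
  α = 10⁻³; a Benjamini–Hochberg helper is provided as an option.
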