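"""File formats, run configuration and the supplementary-dataset loader.

NIfTI is the only volumetric format (written uncompressed for
byte-reproducibility), CSV carries profiles and tables, JSON carries
configuration and QC.  Every CSV/JSON output embeds the run-config hash so
outputs can be traced to the exact configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import CordVolume, CordMask
from .standardize import STANDARD_LENGTH

__all__ = [
    "RunConfig",
    "read_volume",
    "read_mask",
    "write_nifti",
    "write_matrix_csv",
    "read_matrix_csv",
    "load_s1_dataset",
    "S1DatasetError",
]

AXIS_NOTE = "axes: (R-L, A-P, I-S); slice 0 = most inferior; 0-based indices"


@dataclass
class RunConfig:
    """All pipeline knobs in one serializable record."""

    cohort_dir: str = "."
    out_dir: str = "out"
    standard_length: int = STANDARD_LENGTH
    angular_resolution_deg: float = 5.0
    n_perm: int = 100_000
    alpha: float = 1e-3
    seed: int = 0
    level_boundaries: list[float] | None = None
    side: str = "decrease"
    statistic: str = "mean_difference"
    bias_poly_order: int = 0          # 0 disables the bias-correction stand-in
    target_voxel_mm: float = 0.3
    skip_segmentation: bool = False
    masks_dir: str | None = None
    t_low_q: float = 0.5
    t_high_q: float = 0.5

    def __post_init__(self) -> None:
        if 360.0 % self.angular_resolution_deg != 0:
            raise ValueError("360 must be divisible by the angular resolution")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path) -> None:
        d = self.to_dict()
        d["config_hash"] = self.hash()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        d.pop("config_hash", None)
        return cls(**d)


# ---------------------------------------------------------------------------
# NIfTI


def _affine(voxel_mm) -> np.ndarray:
    aff = np.diag([*voxel_mm, 1.0])
    return aff


def write_nifti(obj: CordVolume | CordMask, path, config_hash: str = "") -> None:
    """Write a volume or mask as uncompressed NIfTI (.nii recommended)."""
    data = obj.data.astype(np.float32) if isinstance(obj, CordVolume) else obj.data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine(obj.voxel_mm))
    img.header["descrip"] = f"cfg:{config_hash}".encode()[:79]
    nib.save(img, str(path))


def read_volume(path) -> CordVolume:
    img = nib.load(str(path))
    return CordVolume(np.asarray(img.dataobj, dtype=np.float64),
                      tuple(round(float(z), 6) for z in img.header.get_zooms()[:3]))


def read_mask(path) -> CordMask:
    img = nib.load(str(path))
    return CordMask(np.asarray(img.dataobj) > 0.5,
                    tuple(round(float(z), 6) for z in img.header.get_zooms()[:3]))


# ---------------------------------------------------------------------------
# CSV with provenance comments


def write_matrix_csv(values: np.ndarray, path, config_hash: str = "",
                     columns=None, extra_comments: tuple[str, ...] = ()) -> None:
    """Write a 1D/2D array as CSV with '#' provenance comments on top."""
    values = np.asarray(values)
    if values.ndim == 1:
        df = pd.DataFrame({"value": values})
    else:
        cols = columns if columns is not None else [str(i) for i in range(values.shape[1])]
        df = pd.DataFrame(values, columns=cols)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n# {AXIS_NOTE}\n")
        for line in extra_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index_label="slice", lineterminator="\n")


def read_matrix_csv(path) -> np.ndarray:
    df = pd.read_csv(path, comment="#", index_col=0)
    arr = df.to_numpy(dtype=float)
    return arr[:, 0] if arr.shape[1] == 1 else arr


# ---------------------------------------------------------------------------
# supplementary MAT-file loader (schema-discovering, read-only)


class S1DatasetError(FileNotFoundError):
    pass


_CLINICAL_TOKENS = {
    "mmt_c5": ("mmt_c5", "mmtc5", "c5"),
    "mmt_c6": ("mmt_c6", "mmtc6", "c6"),
    "mmt_c7": ("mmt_c7", "mmtc7", "c7"),
    "mmt_c8": ("mmt_c8", "mmtc8", "c8"),
    "mmt_arm": ("mmt_arm", "arm"),
    "mmt_leg": ("mmt_leg", "leg"),
    "mmt_total": ("mmt_total", "total"),
    "mfm_d1": ("mfm_d1", "d1"),
    "mfm_d2": ("mfm_d2", "d2"),
    "mfm_d3": ("mfm_d3", "d3"),
    "alsfrs_arm": ("alsfrs_arm",),
    "alsfrs_leg": ("alsfrs_leg",),
    "alsfrs_total": ("alsfrs_total", "alsfrs"),
    "disease_duration_years": ("disease_duration_years", "duration"),
    "age": ("age",),
    "sex": ("sex", "gender"),
    "group": ("group", "diagnosis", "status"),
}


def _load_mat_any(path: Path) -> dict:
    """Read a MAT file whatever its version (scipy for <=v7, h5py for v7.3)."""
    try:
        from scipy.io import loadmat

        raw = loadmat(str(path), squeeze_me=True, struct_as_record=False)
        return {k: v for k, v in raw.items() if not k.startswith("__")}
    except NotImplementedError:
        import h5py

        out: dict = {}
        with h5py.File(path, "r") as fh:
            def visit(name, node):
                if isinstance(node, h5py.Dataset):
                    out[name.replace("/", ".")] = node[()]
            fh.visititems(visit)
        return out


def _flatten(obj, prefix="") -> dict:
    """Flatten MAT structs into a {dotted_name: array} dict."""
    out = {}
    if hasattr(obj, "_fieldnames"):  # scipy mat_struct
        for f in obj._fieldnames:
            out.update(_flatten(getattr(obj, f), f"{prefix}{f}."))
    elif isinstance(obj, dict):
        for k, v in obj.items():
            out.update(_flatten(v, f"{prefix}{k}."))
    else:
        out[prefix.rstrip(".")] = obj
    return out


def load_s1_dataset(path) -> tuple[list[dict], dict]:
    """Load the supplementary MAT dataset into subject records + raw sidecar.

    The file's internal structure is undocumented, so the loader is
    schema-discovering: variables are flattened, matched against known
    clinical-field tokens, and any per-subject numeric vectors of a common
    length become record columns.  Everything it cannot interpret stays in
    the raw dict.  A schema report is printed.

    Returns ``(records, raw)`` where ``records`` is a list of per-subject
    dicts (with at least ``id`` and, when discoverable, ``group``).
    """
    path = Path(path)
    if not path.exists():
        raise S1DatasetError(
            f"supplementary dataset not found at {path}; expected the study's "
            "S1 MAT-file with individual MRI data, demographics and clinical "
            "features"
        )
    raw = {}
    for k, v in _load_mat_any(path).items():
        raw.update(_flatten(v, f"{k}."))

    # candidate per-subject vectors: 1-D arrays sharing the modal length
    vectors = {k: np.atleast_1d(np.squeeze(np.asarray(v)))
               for k, v in raw.items()
               if np.asarray(v).size > 1 and np.squeeze(np.asarray(v)).ndim == 1}
    if not vectors:
        raise S1DatasetError(f"no per-subject vectors discovered in {path}")
    lengths = [v.shape[0] for v in vectors.values()]
    n_subj = int(np.bincount(lengths).argmax())
    vectors = {k: v for k, v in vectors.items() if v.shape[0] == n_subj}

    def match(colname: str) -> str | None:
        low = colname.lower()
        for canon, tokens in _CLINICAL_TOKENS.items():
            for tok in tokens:
                if low == tok or low.endswith("." + tok) or low.endswith("_" + tok):
                    return canon
        return None

    records = [{"id": f"sub-{i + 1:02d}"} for i in range(n_subj)]
    mapped = {}
    for name, vec in vectors.items():
        canon = match(name)
        if canon is None:
            continue
        mapped[name] = canon
        for i in range(n_subj):
            val = vec[i]
            records[i][canon] = val.item() if hasattr(val, "item") else val

    for rec in records:
        g = rec.get("group")
        if isinstance(g, (int, float, np.integer, np.floating)):
            rec["group"] = "patient" if g else "control"
        elif isinstance(g, str):
            rec["group"] = "patient" if g.lower().startswith(("p", "sma")) else "control"

    print(f"[s1-loader] {path.name}: {n_subj} subjects; "
          f"mapped {len(mapped)} variables: {sorted(set(mapped.values()))}; "
          f"{len(raw) - len(mapped)} left raw")
    return records, raw
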