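"""Group comparison and clinical statistics for cord profiles.

* site-wise one-sided permutation tests of patient-vs-control decrease
  (default 100,000 permutations, supra-significance alpha = 1e-3, add-one
  p estimator so the attainable floor is 1/(n_perm+1))
* per-slice atrophy-rate profile: 100 * (mean control - mean patient) /
  mean control CSA
* site-wise Spearman correlation maps against clinical scores (exact
  permutation null for n <= 10, t approximation otherwise)
* per-subject rostro-caudal CSA slope vs proximal-distal MMT slope
  correlation
* paired Wilcoxon signed-rank test of proximal (C5) vs distal (C8)
  MMT percent scores
* cohort summary table (mean +/- SD per clinical field)

No multiple-testing correction is applied beyond the stringent alpha; an
optional Benjamini-Hochberg flag is provided for completeness.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import islice, permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .morphometry import CSAProfile, RDProfile, VertebralLevelMap

__all__ = [
    "ComparisonMap",
    "AtrophyRateProfile",
    "CorrelationMap",
    "permutation_map",
    "atrophy_rate",
    "correlate_profiles",
    "gradient_correlation",
    "proximal_distal_test",
    "table1_summary",
    "bh_fdr",
]

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 100_000
DEFAULT_ALPHA = 1e-3

MMT_MAX = {"c5": 10.0, "c6": 10.0, "c7": 30.0, "c8": 20.0}


@dataclass
class ComparisonMap:
    """Site-wise permutation-test result (L vector for CSA, L x 72 for RD)."""

    p_values: np.ndarray
    statistic: np.ndarray
    n_permutations: int
    alpha: float = DEFAULT_ALPHA
    side: str = "decrease"

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        self.statistic = np.asarray(self.statistic, dtype=float)
        if ((self.p_values <= 0) | (self.p_values > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")

    @property
    def significant(self) -> np.ndarray:
        return self.p_values < self.alpha

    @property
    def min_attainable_p(self) -> float:
        return 1.0 / (self.n_permutations + 1)


@dataclass
class AtrophyRateProfile:
    """Per-slice atrophy rate in percent of the mean control CSA."""

    rate_pct: np.ndarray
    mean_control: np.ndarray
    mean_patient: np.ndarray

    def significant_range(self, cmap: ComparisonMap) -> tuple[float, float]:
        """(min, max) rate over slices significant in ``cmap``."""
        sig = cmap.significant
        if not sig.any():
            return (math.nan, math.nan)
        vals = self.rate_pct[sig]
        return float(vals.min()), float(vals.max())


def _stack(profiles) -> np.ndarray:
    arrs = [p.values if isinstance(p, (RDProfile, CSAProfile)) else np.asarray(p)
            for p in profiles]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"profiles have mismatched shapes: {sorted(shapes)}")
    return np.stack([a.astype(float) for a in arrs])


def permutation_map(
    patients,
    controls,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
    side: str = "decrease",
    shared_shuffles: bool = True,
) -> ComparisonMap:
    """One-sided permutation test of patient decrease at every site.

    The statistic at each site is ``T = mean(controls) - mean(patients)``;
    large T means atrophy.  Group labels are randomly reassigned (fixed
    group sizes) ``n_perm`` times and the p-value is the add-one estimate
    ``(1 + #{T* >= T}) / (n_perm + 1)``, so the smallest attainable p is
    ``1/(n_perm+1)``.  By default one shuffle sequence is shared across all
    sites (one relabeling evaluates every site); set
    ``shared_shuffles=False`` for independent per-site streams.
    """
    pat = _stack(patients)
    ctl = _stack(controls)
    if pat.shape[1:] != ctl.shape[1:]:
        raise ValueError("patient and control profiles must share a shape")
    if pat.shape[0] < 2 or ctl.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p-values will be coarse")
    if side != "decrease":
        raise ValueError("only the one-sided 'decrease' alternative is supported")

    site_shape = pat.shape[1:]
    X = np.concatenate([ctl, pat]).reshape(ctl.shape[0] + pat.shape[0], -1)
    n_c, n_p = ctl.shape[0], pat.shape[0]
    n = n_c + n_p
    n_sites = X.shape[1]

    w_obs = np.concatenate([np.full(n_c, 1.0 / n_c), np.full(n_p, -1.0 / n_p)])
    t_obs = w_obs @ X

    rng = np.random.default_rng(seed)
    count = np.zeros(n_sites, dtype=np.int64)
    eps = 1e-12 * max(1.0, float(np.abs(t_obs).max()))

    chunk = max(1, int(4e6) // max(n_sites, 1))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        if shared_shuffles:
            order = rng.random((m, n)).argsort(axis=1)
            W = np.where(order < n_c, 1.0 / n_c, -1.0 / n_p)
            t_perm = W @ X
            count += (t_perm >= t_obs - eps).sum(axis=0)
        else:
            for s in range(n_sites):
                order = rng.random((m, n)).argsort(axis=1)
                W = np.where(order < n_c, 1.0 / n_c, -1.0 / n_p)
                t_perm = W @ X[:, s]
                count[s] += int((t_perm >= t_obs[s] - eps).sum())
        done += m

    p = (count + 1.0) / (n_perm + 1.0)
    sep = np.sqrt(p * (1.0 - p) / n_perm)
    logger.info(
        "permutation_map: %d sites, %d permutations, median SEp=%.2e",
        n_sites, n_perm, float(np.median(sep)),
    )
    return ComparisonMap(
        p_values=p.reshape(site_shape),
        statistic=t_obs.reshape(site_shape),
        n_permutations=n_perm,
        alpha=alpha,
        side=side,
    )


def atrophy_rate(patients, controls) -> AtrophyRateProfile:
    """Per-slice rate: 100 * (mean control - mean patient) / mean control."""
    pat = _stack(patients)
    ctl = _stack(controls)
    if pat.shape[1:] != ctl.shape[1:]:
        raise ValueError("patient and control profiles must share a shape")
    mc = ctl.mean(axis=0)
    mp = pat.mean(axis=0)
    if (mc <= 0).any():
        raise ValueError("mean control CSA must be > 0 everywhere")
    rate = 100.0 * (mc - mp) / mc
    return AtrophyRateProfile(rate_pct=rate, mean_control=mc, mean_patient=mp)


# ---------------------------------------------------------------------------
# Spearman correlation maps


def _rank(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return sps.rankdata(a, axis=axis, method="average")


def spearman_rho(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Spearman rho of ``x`` (n,) against each column of ``Y`` (n, m).

    Rank-then-Pearson with average ranks; columns with zero variance give
    NaN.
    """
    rx = _rank(x)
    rY = _rank(Y, axis=0)
    rx = rx - rx.mean()
    rY = rY - rY.mean(axis=0)
    denom = np.sqrt((rx**2).sum() * (rY**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, rx @ rY / denom, np.nan)


@dataclass
class CorrelationMap:
    """Site-wise Spearman correlation against one clinical score."""

    rho: np.ndarray
    p_values: np.ndarray
    n: int
    alpha: float = DEFAULT_ALPHA
    flagged_sites: np.ndarray = field(default=None)

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(np.isnan(self.p_values), False, self.p_values < self.alpha)


def _exact_spearman_p(scores: np.ndarray, Y: np.ndarray, rho_obs: np.ndarray,
                      chunk: int = 40_320) -> np.ndarray:
    """Two-sided exact permutation p for Spearman rho (enumerates n!)."""
    n = len(scores)
    rY = _rank(Y, axis=0)
    rYc = rY - rY.mean(axis=0)
    ry_ss = (rYc**2).sum(axis=0)
    rx = _rank(scores)
    rx_ss = ((rx - rx.mean()) ** 2).sum()

    count = np.zeros(Y.shape[1], dtype=np.int64)
    total = 0
    it = permutations(rx)
    while True:
        block = np.array(list(islice(it, chunk)))
        if block.size == 0:
            break
        bc = block - block.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho_null = (bc @ rYc) / np.sqrt(rx_ss * ry_ss)
        count += (np.abs(rho_null) >= np.abs(rho_obs) - 1e-12).sum(axis=0)
        total += len(block)
    return count / total


def correlate_profiles(
    profiles,
    scores,
    alpha: float = DEFAULT_ALPHA,
    exact_max_n: int = 10,
) -> CorrelationMap:
    """Spearman correlation of per-subject profiles with one clinical score.

    Subjects with missing (NaN) scores are dropped.  For n <= ``exact_max_n``
    the two-sided p-value comes from the exact permutation distribution of
    rho (all n! relabelings); otherwise from the t approximation.  Sites
    where rho is undefined (constant profile or score) are flagged and get
    NaN.
    """
    X = _stack(profiles)
    scores = np.asarray(scores, dtype=float)
    if len(scores) != X.shape[0]:
        raise ValueError("one score per subject required")
    keep = np.isfinite(scores)
    X, scores = X[keep], scores[keep]
    n = len(scores)
    if n < 4:
        raise ValueError("need at least 4 subjects with scores")

    site_shape = X.shape[1:]
    Y = X.reshape(n, -1)
    rho = spearman_rho(scores, Y)
    flagged = ~np.isfinite(rho)
    if np.ptp(scores) == 0:
        rho[:] = np.nan
        flagged[:] = True

    p = np.full_like(rho, np.nan)
    ok = ~flagged
    if ok.any():
        if n <= exact_max_n:
            p[ok] = _exact_spearman_p(scores, Y[:, ok], rho[ok])
        else:
            r = rho[ok]
            with np.errstate(divide="ignore", invalid="ignore"):
                t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-15, None))
            p[ok] = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
            p[ok] = np.clip(p[ok], np.finfo(float).tiny, 1.0)
    return CorrelationMap(
        rho=rho.reshape(site_shape),
        p_values=p.reshape(site_shape),
        n=n,
        alpha=alpha,
        flagged_sites=flagged.reshape(site_shape),
    )


def gradient_correlation(
    csa_profiles,
    levels: VertebralLevelMap,
    mmt_pct: np.ndarray,
    voxel_mm_z: float = 0.3,
) -> tuple[float, float]:
    """Correlate per-subject CSA slope (C4 -> C7) with MMT slope (C5 -> C8).

    For each subject the CSA slope is the ordinary-least-squares slope of
    CSA against position in mm over the slices assigned to vertebral levels
    C4-C7, and the MMT slope is the OLS slope of the four percent subscores
    (C5..C8 spinal levels) against 1..4.  The two slope vectors are then
    Spearman-correlated across subjects.  Returns ``(rho, p)``; constant
    slopes make rho undefined and return NaN.
    """
    X = _stack(csa_profiles)
    mmt = np.asarray(mmt_pct, dtype=float)
    if mmt.ndim != 2 or mmt.shape[1] != 4:
        raise ValueError("mmt_pct must be (n_subjects, 4): C5..C8 percent")
    if X.shape[0] != mmt.shape[0]:
        raise ValueError("profiles and scores must cover the same subjects")
    if X.shape[0] < 4:
        raise ValueError("need at least 4 subjects")

    sl = levels.span_slices("C4", "C7")
    x_mm = sl * voxel_mm_z
    csa_slopes = np.polyfit(x_mm, X[:, sl].T, deg=1)[0]
    mmt_slopes = np.polyfit(np.arange(1, 5, dtype=float), mmt.T, deg=1)[0]

    if np.ptp(csa_slopes) == 0 or np.ptp(mmt_slopes) == 0:
        return (math.nan, math.nan)
    res = sps.spearmanr(csa_slopes, mmt_slopes)
    return float(res.statistic), float(res.pvalue)


def proximal_distal_test(mmt_pct_c5, mmt_pct_c8) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of paired C5 vs C8 percent scores.

    Zero differences are dropped; the exact distribution is used for
    n <= 25 pairs (falling back to the normal approximation when tied
    absolute differences make the exact distribution unavailable).  All
    pairs tied returns ``(0.0, 1.0)`` by convention.
    """
    c5 = np.asarray(mmt_pct_c5, dtype=float)
    c8 = np.asarray(mmt_pct_c8, dtype=float)
    if c5.shape != c8.shape:
        raise ValueError("paired scores required")
    d = c5 - c8
    d = d[d != 0]
    if d.size == 0:
        logger.warning("proximal_distal_test: all pairs tied; p = 1 by convention")
        return (0.0, 1.0)
    method = "exact" if d.size <= 25 and len(np.unique(np.abs(d))) == d.size else "auto"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                       method=method)
    return (float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------


TABLE_FIELDS = [
    ("age", "Age (years)"),
    ("disease_duration_years", "Disease duration (years)"),
    ("mmt_arm", "MMT arm (/70)"),
    ("mmt_leg", "MMT leg (/70)"),
    ("mmt_total", "MMT total (/140)"),
    ("mmt_c5", "MMT C5 spinal level (/10)"),
    ("mmt_c6", "MMT C6 spinal level (/10)"),
    ("mmt_c7", "MMT C7 spinal level (/30)"),
    ("mmt_c8", "MMT C8 spinal level (/20)"),
    ("mmt_pct_c5", "MMT percent change C5 (%)"),
    ("mmt_pct_c6", "MMT percent change C6 (%)"),
    ("mmt_pct_c7", "MMT percent change C7 (%)"),
    ("mmt_pct_c8", "MMT percent change C8 (%)"),
    ("mfm_d1", "MFM D1 (/39)"),
    ("mfm_d2", "MFM D2 (/39)"),
    ("mfm_d3", "MFM D3 (/39)"),
    ("alsfrs_arm", "ALSFRS-R arm (/8)"),
    ("alsfrs_leg", "ALSFRS-R leg (/8)"),
    ("alsfrs_total", "ALSFRS-R total (/48)"),
]


def mmt_percent(score: float, level: str) -> float:
    """Percent-of-maximum for one MMT level subscore (C5/C6 /10, C7 /30, C8 /20)."""
    return 100.0 * score / MMT_MAX[level.lower()]


def table1_summary(records) -> pd.DataFrame:
    """Cohort summary: mean +/- SD per clinical field and group.

    ``records`` is a list of per-subject dicts (or a DataFrame) with at
    least ``group``; missing fields are reported as NA with a count.
    Percent-change rows are derived from raw subscores when absent.
    """
    df = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    if "group" not in df:
        raise ValueError("records must carry a 'group' field")
    for lvl, mx in MMT_MAX.items():
        raw = f"mmt_{lvl}"
        pct = f"mmt_pct_{lvl}"
        if pct not in df and raw in df:
            df[pct] = 100.0 * df[raw] / mx

    rows = []
    for group, gdf in df.groupby("group"):
        rows.append({"group": group, "field": "n", "label": "Number",
                     "mean": float(len(gdf)), "sd": 0.0, "n_missing": 0})
        for fieldname, label in TABLE_FIELDS:
            if fieldname not in gdf:
                rows.append({"group": group, "field": fieldname, "label": label,
                             "mean": math.nan, "sd": math.nan,
                             "n_missing": len(gdf)})
                continue
            col = pd.to_numeric(gdf[fieldname], errors="coerce")
            n_missing = int(col.isna().sum())
            rows.append({
                "group": group, "field": fieldname, "label": label,
                "mean": float(col.mean()) if n_missing < len(gdf) else math.nan,
                "sd": float(col.std(ddof=1)) if n_missing < len(gdf) - 1 else math.nan,
                "n_missing": n_missing,
            })
    return pd.DataFrame(rows)


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg rejection mask (optional; not the default procedure)."""
    p = np.asarray(p_values, dtype=float).ravel()
    m = np.isfinite(p).sum()
    order = np.argsort(p)
    thresh = q * (np.arange(1, len(p) + 1)) / m
    passed = p[order] <= thresh
    k = np.nonzero(passed)[0]
    out = np.zeros(len(p), dtype=bool)
    if k.size:
        out[order[: k.max() + 1]] = True
    return out.reshape(np.shape(p_values))
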