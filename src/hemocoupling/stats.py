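"""Group-level statistics.

The symptom covariates are *mutually residualized*: the fatigue score is the
residual of FSS after regressing out the depression score within the patient
group, and vice versa, so each model isolates the unique contribution of one
symptom dimension.  Total intracranial volume (TIV) is the nuisance
covariate throughout.

Voxel-wise maps relate a per-subject image (lag or ICC) to a residualized
score by partial correlation controlling TIV — equivalent to the one-
covariate-plus-nuisance GLM contrast — thresholded at an uncorrected voxel p
with a connected-component cluster-extent filter (18-connectivity default).
Region-level metrics use partial correlations with optional extra nuisances
(e.g. total GM and lesion volume for robustness checks).  Median-split
subgroup contrasts compare high- vs low-scoring patients and each subgroup
against healthy-control reference values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import PipelineConfig, ValidationError, voxel_to_world

__all__ = [
    "ResidualScores", "StatMap", "RegionStatResult", "ContrastResult",
    "residualize", "residualized_scores", "partial_corr",
    "voxelwise_covariate_map", "region_partial_corr", "median_split_contrast",
    "label_clusters",
]


# ---------------------------------------------------------------------------
# Residualization and partial correlation
# ---------------------------------------------------------------------------

def _ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of y against [1 | x] (x may be (n,) or (n, k))."""
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != y.shape[0]:
        x = x.T
    design = np.column_stack([np.ones(y.shape[0]), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def residualize(scores: pd.DataFrame, target: str, nuisance: str,
                group: str | None = None) -> pd.Series:
    """Residual of ``target`` after OLS on ``nuisance`` within ``group``.

    Rows outside the group or with missing values get NaN; residuals are in
    the target's original units.
    """
    df = scores if group is None else scores[scores["group"] == group]
    complete = df[[target, nuisance]].dropna()
    if len(complete) < 3:
        raise ValidationError(
            f"need >= 3 complete cases to residualize {target} on {nuisance}"
        )
    if complete[nuisance].std() == 0:
        raise ValidationError(f"nuisance column {nuisance!r} is constant")
    resid = _ols_residuals(complete[target].to_numpy(),
                           complete[nuisance].to_numpy())
    out = pd.Series(np.nan, index=scores.index, name=f"{target}_resid")
    out.loc[complete.index] = resid
    return out


@dataclass
class ResidualScores:
    """Mutually adjusted symptom scores for one patient group."""

    group: str
    table: pd.DataFrame  # subject_id, fss_resid, hads_resid

    def column(self, name: str) -> pd.Series:
        return self.table.set_index("subject_id")[name]


def residualized_scores(cohort: pd.DataFrame, group: str) -> ResidualScores:
    """FSS adjusted for HADS-D and HADS-D adjusted for FSS, within a group."""
    fss_r = residualize(cohort, "fss", "hads_d", group)
    hads_r = residualize(cohort, "hads_d", "fss", group)
    sub = cohort[cohort["group"] == group]
    table = pd.DataFrame({
        "subject_id": sub["subject_id"].to_numpy(),
        "fss_resid": fss_r.loc[sub.index].to_numpy(),
        "hads_resid": hads_r.loc[sub.index].to_numpy(),
    })
    return ResidualScores(group=group, table=table)


def partial_corr(x: np.ndarray, y: np.ndarray,
                 nuisance: np.ndarray) -> tuple[float, float, int]:
    """Partial Pearson correlation of x and y controlling for nuisance(s).

    Computed by double residualization (correlation of the two residual
    vectors), which is algebraically identical to the precision-matrix
    formula.  Returns (r, two-sided p, n); df = n - 2 - k for k nuisances.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.atleast_2d(np.asarray(nuisance, float))
    if z.shape[0] != x.shape[0]:
        z = z.T
    n, k = z.shape
    if x.shape[0] != n or y.shape[0] != n:
        raise ValidationError("x, y and nuisance must have equal length")
    if n < 4 + k:
        raise ValidationError(f"need >= {4 + k} complete cases, got {n}")
    rx = _ols_residuals(x, z)
    ry = _ols_residuals(y, z)
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    if sx == 0 or sy == 0:
        return np.nan, np.nan, n
    r = float(np.clip(rx @ ry / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    t = r * np.sqrt(df / max(1.0 - r * r, 1e-15))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p, n


# ---------------------------------------------------------------------------
# Voxel-wise maps with cluster-extent thresholding
# ---------------------------------------------------------------------------

_STRUCTURES = {6: ndimage.generate_binary_structure(3, 1),
               18: ndimage.generate_binary_structure(3, 2),
               26: ndimage.generate_binary_structure(3, 3)}


@dataclass
class StatMap:
    """Voxel-wise effect map with significance and surviving clusters."""

    effect: np.ndarray
    p: np.ndarray
    surviving: np.ndarray
    clusters: list[dict] = field(default_factory=list)
    n: int = 0


def label_clusters(mask: np.ndarray, connectivity: int = 18) -> tuple[np.ndarray, int]:
    """Connected components of a boolean grid (6/18/26-connectivity)."""
    try:
        structure = _STRUCTURES[connectivity]
    except KeyError:
        raise ValidationError("connectivity must be 6, 18 or 26") from None
    return ndimage.label(mask, structure=structure)


def voxelwise_covariate_map(maps: np.ndarray, covariate: np.ndarray,
                            nuisance: np.ndarray, config: PipelineConfig,
                            mask: np.ndarray | None = None,
                            affine: np.ndarray | None = None) -> StatMap:
    """Partial correlation of per-subject maps with a score, voxel by voxel.

    ``maps`` is (n_subjects, x, y, z).  Per voxel the map value is
    correlated with ``covariate`` controlling for ``nuisance`` (TIV);
    two-sided p from the t transform with n-3 df.  Voxels at p < voxel_p
    are kept only inside connected components of at least ``cluster_min``
    voxels.
    """
    maps = np.asarray(maps, float)
    n = maps.shape[0]
    if n < 5:
        raise ValidationError(f"need >= 5 subjects, got {n}")
    cov = np.asarray(covariate, float)
    nui = np.asarray(nuisance, float)
    if cov.shape[0] != n or nui.shape[0] != n:
        raise ValidationError("covariate/nuisance length must match subjects")
    shape = maps.shape[1:]
    m = np.ones(shape, bool) if mask is None else mask.astype(bool)

    y = maps[:, m]                          # (n, V)
    ry = _ols_residuals(y, nui)
    rc = _ols_residuals(cov, nui)
    sy = np.linalg.norm(ry, axis=0)
    sc = np.linalg.norm(rc)
    ok = (sy > 0) & (sc > 0)
    r = np.zeros(y.shape[1])
    r[ok] = np.clip((rc @ ry[:, ok]) / (sy[ok] * sc), -1.0, 1.0)
    df = n - 3
    t = r * np.sqrt(df / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[~ok] = 1.0

    effect = np.zeros(shape)
    p_grid = np.ones(shape)
    effect[m] = r
    p_grid[m] = p

    supra = m & (p_grid < config.voxel_p)
    labels, n_lab = label_clusters(supra, config.cluster_connectivity)
    surviving = np.zeros(shape, bool)
    clusters = []
    for lab in range(1, n_lab + 1):
        cmask = labels == lab
        size = int(cmask.sum())
        if size < config.cluster_min:
            continue
        surviving |= cmask
        idx = np.argwhere(cmask)
        peak = idx[np.argmax(np.abs(effect[cmask]))]
        entry = {"label": lab, "size": size, "peak_voxel": peak.tolist(),
                 "peak_effect": float(effect[tuple(peak)])}
        if affine is not None:
            entry["peak_mm"] = voxel_to_world(affine, peak).tolist()
        clusters.append(entry)
    clusters.sort(key=lambda c: -abs(c["peak_effect"]))
    return StatMap(effect=effect, p=p_grid, surviving=surviving,
                   clusters=clusters, n=n)


# ---------------------------------------------------------------------------
# Region-level statistics
# ---------------------------------------------------------------------------

@dataclass
class RegionStatResult:
    region: int
    metric: str
    r: float
    p: float
    n: int
    significant: bool


def region_partial_corr(table: pd.DataFrame, metric_cols: list[str],
                        covariate: pd.Series, nuisance: pd.Series,
                        config: PipelineConfig,
                        extra_nuisances: pd.DataFrame | None = None
                        ) -> list[RegionStatResult]:
    """Partial correlation of each region x metric with a score.

    ``table`` has one row per (subject, region) with the metric columns;
    ``covariate`` / ``nuisance`` are indexed by subject_id.  Complete cases
    only; significance flagged at ``config.region_p``.  Constant metric
    columns yield NaN results flagged non-significant.
    """
    results = []
    for rid, sub in table.groupby("region"):
        sub = sub.set_index("subject_id")
        for metric in metric_cols:
            frame = pd.DataFrame({
                "m": sub[metric],
                "c": covariate.reindex(sub.index),
                "n0": nuisance.reindex(sub.index),
            })
            if extra_nuisances is not None:
                for col in extra_nuisances.columns:
                    frame[col] = extra_nuisances[col].reindex(sub.index)
            frame = frame.dropna()
            k = frame.shape[1] - 2
            if len(frame) < 4 + k or frame["m"].std() == 0:
                results.append(RegionStatResult(int(rid), metric, np.nan,
                                                np.nan, len(frame), False))
                continue
            nuis = frame.drop(columns=["m", "c"]).to_numpy()
            r, p, n = partial_corr(frame["m"].to_numpy(),
                                   frame["c"].to_numpy(), nuis)
            results.append(RegionStatResult(int(rid), metric, r, p, n,
                                            bool(p < config.region_p)))
    return results


def benjamini_hochberg(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """BH step-up rejection mask (optional extra correction, off by default)."""
    p = np.asarray(pvals, float)
    order = np.argsort(p)
    m = len(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    out = np.zeros(m, bool)
    out[order[:k]] = True
    return out


# ---------------------------------------------------------------------------
# Median-split subgroup contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    """High-vs-low median split and comparisons against a reference group."""

    median: float
    n_low: int
    n_high: int
    high_vs_low: dict
    high_vs_reference: dict | None = None
    low_vs_reference: dict | None = None


def _two_sample(a: np.ndarray, b: np.ndarray, method: str) -> dict:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if method == "welch":
        t, p = stats.ttest_ind(a, b, equal_var=False)
        stat_name = "t"
        stat = float(t)
    elif method == "mannwhitney":
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat_name = "U"
        stat = float(u)
    else:
        raise ValidationError(f"unknown test {method!r}")
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    d = float((a.mean() - b.mean()) / pooled) if pooled > 0 else np.nan
    return {stat_name: stat, "p": float(p), "cohens_d": d,
            "mean_diff": float(a.mean() - b.mean())}


def median_split_contrast(cohort: pd.DataFrame, score: str, metric: pd.Series,
                          group: str, reference: np.ndarray | None = None,
                          method: str = "welch") -> ContrastResult:
    """Split one patient group at its median score and contrast the metric.

    Scores equal to the median go to the low side.  ``metric`` is indexed by
    subject_id; ``reference`` holds the same metric in healthy controls.
    """
    sub = cohort[cohort["group"] == group].dropna(subset=[score])
    scores = sub.set_index("subject_id")[score]
    if scores.nunique() < 2:
        raise ValidationError(f"all {score} scores identical in group {group}")
    med = float(scores.median())
    low_ids = scores.index[scores <= med]
    high_ids = scores.index[scores > med]
    if len(low_ids) < 3 or len(high_ids) < 3:
        raise ValidationError(
            f"median split leaves a side with < 3 subjects "
            f"({len(low_ids)} low / {len(high_ids)} high)"
        )
    vals = metric
    low = vals.reindex(low_ids).dropna().to_numpy()
    high = vals.reindex(high_ids).dropna().to_numpy()
    res = ContrastResult(
        median=med, n_low=len(low), n_high=len(high),
        high_vs_low=_two_sample(high, low, method),
    )
    if reference is not None and len(reference) >= 3:
        ref = np.asarray(reference, float)
        res.high_vs_reference = _two_sample(high, ref, method)
        res.low_vs_reference = _two_sample(low, ref, method)
    return res
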