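"""Per-layer preprocessing: clean, log2, median-center, filter, impute, QC.

The canonical stage order is::

    clean -> log2_transform -> median_center -> detection_filter -> impute_ensemble

Cleaning collapses duplicate feature ids (keeping the row with the highest
total detected intensity) and converts zero/negative/non-finite entries to
missing -- in MS exports a reported zero means "not detected", not a true
zero.  Median centering subtracts each sample's observed median so that
sample-wise intensity shifts (loading, labeling efficiency) cancel.

Imputation is a transparent, seeded three-component ensemble in the spirit
of ensemble imputers for left-censored proteomics data:

a. feature-space kNN (k=10, Spearman-correlation distance between feature
   profiles), averaging the neighbours' observed values in the target sample;
b. a left-censored draw N(q1_sample - 0.5, 0.3 * sample sd) used when a
   feature has no observed value anywhere in the sample's replicate group
   (the classic MNAR signature of an undetected analyte);
c. the feature's observed median.

Each missing cell receives the mean of the applicable component estimates;
observed cells are never altered.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import IntensityMatrix, replicate_groups

__all__ = [
    "clean",
    "log2_transform",
    "median_center",
    "detection_filter",
    "impute_ensemble",
    "qc",
    "QCReport",
    "preprocess_layer",
]

# cap on the feature-kNN donor pool so imputation stays tractable on large layers
_MAX_KNN_POOL = 4000


def clean(matrix: IntensityMatrix) -> IntensityMatrix:
    """Collapse duplicate feature ids and convert non-positive entries to missing."""
    if matrix.scale != "raw":
        raise ValueError("clean() expects a raw-scale matrix")
    if matrix.n_features == 0:
        raise ValueError("empty matrix")
    vals = matrix.values.to_numpy(float).copy()
    vals[~np.isfinite(vals)] = np.nan
    vals[vals <= 0] = np.nan
    df = pd.DataFrame(vals, index=matrix.feature_ids, columns=matrix.sample_ids)

    if df.index.duplicated().any():
        totals = df.sum(axis=1, skipna=True)
        order = pd.DataFrame({"total": totals.to_numpy()}, index=df.index)
        order["pos"] = np.arange(len(df))
        # keep, per id, the row with the highest total detected intensity
        keep_pos = (order.sort_values(["total", "pos"], ascending=[False, True])
                    .groupby(level=0, sort=False)["pos"].first())
        keep_rows = sorted(keep_pos.to_list())
        df = df.iloc[keep_rows]
    return IntensityMatrix.from_values(df, scale="raw", layer=matrix.layer)


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    if matrix.scale != "raw":
        raise ValueError("matrix is already log2-scale")
    out = matrix.copy()
    out.values = np.log2(out.values)
    out.scale = "log2"
    return out


def median_center(matrix: IntensityMatrix) -> IntensityMatrix:
    """Subtract each sample's median of observed values (log2 scale)."""
    if matrix.scale != "log2":
        raise ValueError("median_center() expects a log2-scale matrix")
    medians = matrix.values.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValueError(f"samples with zero observed values: {bad}")
    out = matrix.copy()
    out.values = out.values - medians
    return out


def detection_filter(matrix: IntensityMatrix, min_rate: float = 0.70) -> IntensityMatrix:
    """Keep features detected in at least ceil(min_rate * n_samples) samples."""
    if not 0.0 < min_rate <= 1.0:
        raise ValueError("min_rate must lie in (0, 1]")
    needed = math.ceil(min_rate * matrix.n_samples - 1e-9)
    keep = matrix.detected.sum(axis=1) >= needed
    out = matrix.copy()
    out.values = out.values.loc[keep]
    out.detected = out.detected.loc[keep]
    return out


def _spearman_knn_estimates(vals: np.ndarray, k: int) -> np.ndarray:
    """kNN estimate for every cell, using Spearman distance between features.

    Ranks are computed on rows with missing cells filled by the row median
    (ranking only; the imputation values come from observed cells).  Returns
    an array of the same shape with NaN where no neighbour had an observed
    value in that sample.
    """
    n_feat, n_samp = vals.shape
    obs = np.isfinite(vals)
    row_med = np.nanmedian(vals, axis=1)
    filled = np.where(obs, vals, row_med[:, None])
    ranks = np.apply_along_axis(stats.rankdata, 1, filled)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks ** 2).sum(axis=1))
    norms[norms == 0] = 1.0
    ranks /= norms[:, None]

    # donor pool: most complete features first (deterministic tie-break by row)
    completeness = obs.sum(axis=1)
    pool = np.lexsort((np.arange(n_feat), -completeness))[:_MAX_KNN_POOL]
    corr = ranks @ ranks[pool].T  # n_feat x pool
    # a feature must not be its own neighbour
    pool_pos = {p: j for j, p in enumerate(pool)}
    for i, j in pool_pos.items():
        corr[i, j] = -np.inf

    est = np.full_like(vals, np.nan)
    need_rows = np.where(~obs.all(axis=1))[0]
    for i in need_rows:
        order = np.argsort(-corr[i], kind="stable")[:max(k * 4, k)]
        neighbours = pool[order]
        missing_cols = np.where(~obs[i])[0]
        for j in missing_cols:
            donor_vals = []
            for nb in neighbours:
                if obs[nb, j]:
                    donor_vals.append(vals[nb, j])
                if len(donor_vals) == k:
                    break
            if donor_vals:
                est[i, j] = float(np.mean(donor_vals))
    return est


def impute_ensemble(matrix: IntensityMatrix, seed: int,
                    design: pd.DataFrame | None = None, k: int = 10,
                    ) -> IntensityMatrix:
    """Fill every missing cell with the seeded three-component ensemble mean."""
    if matrix.scale != "log2":
        raise ValueError("impute_ensemble() expects a log2-scale matrix")
    zero_obs = ~matrix.detected.any(axis=1)
    if zero_obs.any():
        raise ValueError("features with zero observed values must be filtered "
                         f"first ({int(zero_obs.sum())} offending features)")
    vals = matrix.values.to_numpy(float)
    obs = np.isfinite(vals)
    if obs.all():
        out = matrix.copy()
        out.is_imputed = True
        return out

    rng = np.random.default_rng(seed)
    est_knn = _spearman_knn_estimates(vals, k=k)
    est_median = np.repeat(np.nanmedian(vals, axis=1)[:, None], vals.shape[1], axis=1)

    # left-censored draws where a feature is entirely missing in a design cell
    est_censor = np.full_like(vals, np.nan)
    if design is not None:
        col_pos = {s: j for j, s in enumerate(matrix.sample_ids)}
        q1 = np.nanpercentile(vals, 1, axis=0)
        s_sd = np.nanstd(vals, axis=0, ddof=1)
        for (_, _), samples in replicate_groups(design).items():
            cols = [col_pos[s] for s in samples if s in col_pos]
            if not cols:
                continue
            group_missing = ~obs[:, cols].any(axis=1)
            for j in cols:
                draw_rows = np.where(group_missing & ~obs[:, j])[0]
                if draw_rows.size:
                    est_censor[draw_rows, j] = rng.normal(
                        q1[j] - 0.5, 0.3 * s_sd[j], size=draw_rows.size)

    stacked = np.stack([est_knn, est_median, est_censor])
    with np.errstate(invalid="ignore"):
        ensemble = np.nanmean(stacked, axis=0)
    filled = np.where(obs, vals, ensemble)
    if not np.isfinite(filled).all():
        # row median always exists (zero-observed rows rejected above)
        raise RuntimeError("imputation left non-finite cells")
    out = matrix.copy()
    out.values = pd.DataFrame(filled, index=matrix.feature_ids,
                              columns=matrix.sample_ids)
    out.is_imputed = True
    return out


# ----------------------------------------------------------------------
# quality control
# ----------------------------------------------------------------------

@dataclass
class QCReport:
    """Replicate-group CVs, sample correlations, intensity quantiles, detection."""

    cv: pd.DataFrame                 # features x (cell_line, condition) groups
    spearman: pd.DataFrame           # samples x samples
    intensity_quantiles: pd.DataFrame  # samples x quantiles
    detection_rate: pd.Series        # per feature

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cv_median_per_group": {str(k): (None if pd.isna(v) else float(v))
                                    for k, v in self.cv.median().items()},
            "spearman": {c: {r: float(self.spearman.loc[r, c])
                             for r in self.spearman.index}
                         for c in self.spearman.columns},
            "intensity_quantiles": {s: {str(q): float(v)
                                        for q, v in row.items()}
                                    for s, row in self.intensity_quantiles.iterrows()},
            "detection_rate_mean": float(self.detection_rate.mean()),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def qc(raw_matrix: IntensityMatrix, design: pd.DataFrame) -> QCReport:
    """QC metrics: CV on raw intensities per replicate group, Spearman on log2."""
    if raw_matrix.scale != "raw":
        raise ValueError("qc() expects raw-scale intensities (CVs are raw-scale)")
    vals = raw_matrix.values

    cv_cols = {}
    for (cl, cond), samples in replicate_groups(design).items():
        cols = [s for s in samples if s in vals.columns]
        if len(cols) < 2:
            cv_cols[f"{cl}/{cond}"] = pd.Series(np.nan, index=vals.index)
            continue
        sub = vals[cols]
        mean = sub.mean(axis=1, skipna=True)
        sd = sub.std(axis=1, ddof=1, skipna=True)
        cv_cols[f"{cl}/{cond}"] = sd / mean
    cv = pd.DataFrame(cv_cols)

    log2_vals = np.log2(vals)
    spearman = log2_vals.corr(method="spearman")

    qs = [0.05, 0.25, 0.5, 0.75, 0.95]
    quantiles = log2_vals.quantile(qs).T
    quantiles.columns = [f"q{int(q * 100)}" for q in qs]

    return QCReport(cv=cv, spearman=spearman, intensity_quantiles=quantiles,
                    detection_rate=raw_matrix.detection_rate())


# ----------------------------------------------------------------------
# convenience chain
# ----------------------------------------------------------------------

def preprocess_layer(matrix: IntensityMatrix, design: pd.DataFrame, seed: int,
                     min_rate: float = 0.70) -> dict:
    """Run the full chain; returns cleaned-raw, filtered and imputed matrices + QC."""
    cleaned = clean(matrix)
    report = qc(cleaned, design)
    logged = log2_transform(cleaned)
    centered = median_center(logged)
    filtered = detection_filter(centered, min_rate=min_rate)
    imputed = impute_ensemble(filtered, seed=seed, design=design)
    raw_filtered = detection_filter(cleaned, min_rate=min_rate)
    return {
        "centered": centered,
        "cleaned_raw": cleaned,
        "raw_filtered": raw_filtered,
        "filtered": filtered,
        "imputed": imputed,
        "qc": report,
    }
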