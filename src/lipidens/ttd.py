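"""Time-to-diagnosis classification of selected features.

For each feature, the pair-level log fold-change (case minus control on
the normalized log scale) is regressed on the pair's time to diagnosis
(ttd).  A flat trajectory (slope p > alpha) marks a potentially causal
feature (C); a significant slope marks the feature reactive (R) when
the fitted |log fold-change| shrinks toward zero across the observed
ttd range, and indeterminate (I) when it grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import study_samples

CLASS_CAUSAL = "C"
CLASS_REACTIVE = "R"
CLASS_INDETERMINATE = "I"


@dataclass
class TtdFit:
    """Simple-linear-regression summary of log fold-change on ttd."""

    feature_id: str
    n: int
    intercept: float
    slope: float
    slope_se: float
    slope_p: float
    resid_sd: float
    ttd_mean: float
    sxx: float

    def predict(self, ttd: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(ttd, dtype=float)

    def confidence_band(self, ttd: np.ndarray, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise confidence band for the regression mean."""
        ttd = np.asarray(ttd, dtype=float)
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        half = tcrit * self.resid_sd * np.sqrt(1.0 / self.n + (ttd - self.ttd_mean) ** 2 / self.sxx)
        fitted = self.predict(ttd)
        return fitted - half, fitted + half


def pair_log_fold_change(
    norm_matrix: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-pair log fold-change matrix and the pair ttd vector.

    Returns ``(logfc, ttd)`` with ``logfc`` indexed by feature and one
    column per pair id; ttd is taken from the case member of each pair.
    """
    study = study_samples(samples)
    study = study.loc[study.index.intersection(norm_matrix.columns)]
    cases = study[study["caco"] == "case"].sort_values("pair_id")
    ctrls = study[study["caco"] == "control"].sort_values("pair_id")
    if len(cases) != len(ctrls) or not (
        cases["pair_id"].to_numpy() == ctrls["pair_id"].to_numpy()
    ).all():
        raise ValueError("every pair needs exactly one case and one control with data")
    ttd = pd.Series(cases["ttd_years"].to_numpy(), index=cases["pair_id"].to_numpy(), name="ttd_years")
    if ttd.isna().any() or (ttd <= 0).any():
        raise ValueError("missing or non-positive ttd")
    diff = norm_matrix[cases.index].to_numpy() - norm_matrix[ctrls.index].to_numpy()
    logfc = pd.DataFrame(diff, index=norm_matrix.index, columns=ttd.index)
    return logfc, ttd


def ttd_regress(ttd: np.ndarray, logfc: np.ndarray, feature_id: str = "") -> TtdFit:
    """OLS of log fold-change on ttd with a two-sided slope t-test."""
    ttd = np.asarray(ttd, dtype=float)
    logfc = np.asarray(logfc, dtype=float)
    n = ttd.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    sxx = float(((ttd - ttd.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("all ttd values equal; slope undefined")
    sxy = float(((ttd - ttd.mean()) * (logfc - logfc.mean())).sum())
    slope = sxy / sxx
    intercept = float(logfc.mean() - slope * ttd.mean())
    resid = logfc - (intercept + slope * ttd)
    rss = float((resid**2).sum())
    resid_sd = np.sqrt(rss / (n - 2))
    se = resid_sd / np.sqrt(sxx)
    if se == 0:
        p = 1.0 if slope == 0 else 0.0
    else:
        p = float(2.0 * stats.t.sf(abs(slope) / se, n - 2))
    return TtdFit(
        feature_id=feature_id,
        n=n,
        intercept=intercept,
        slope=slope,
        slope_se=float(se),
        slope_p=p,
        resid_sd=float(resid_sd),
        ttd_mean=float(ttd.mean()),
        sxx=sxx,
    )


def classify_feature(fit: TtdFit, ttd_min: float, ttd_max: float, alpha: float = 0.05) -> str:
    """C if the slope is not significant; else R if |fitted logFC|
    shrinks from ttd_min to ttd_max, I if it grows or holds."""
    if not np.isfinite(fit.slope):
        raise ValueError("undefined fit")
    if fit.slope_p > alpha:
        return CLASS_CAUSAL
    d_lo = abs(fit.intercept + fit.slope * ttd_min)
    d_hi = abs(fit.intercept + fit.slope * ttd_max)
    return CLASS_REACTIVE if d_hi < d_lo else CLASS_INDETERMINATE


def classify_features(
    norm_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    feature_ids=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit and classify a set of features; returns the per-feature table.

    Columns: intercept, slope, slope_se, slope_p, class.  The ttd range
    used by the magnitude rule is the observed min/max over pairs.
    """
    if feature_ids is None:
        feature_ids = norm_matrix.index
    feature_ids = pd.Index(feature_ids)
    logfc, ttd = pair_log_fold_change(norm_matrix.loc[feature_ids], samples)
    tvals = ttd.to_numpy()
    lo, hi = float(tvals.min()), float(tvals.max())
    rows = []
    for fid in feature_ids:
        fit = ttd_regress(tvals, logfc.loc[fid].to_numpy(), feature_id=fid)
        rows.append(
            {
                "feature_id": fid,
                "n_pairs": fit.n,
                "intercept": fit.intercept,
                "slope": fit.slope,
                "slope_se": fit.slope_se,
                "slope_p": fit.slope_p,
                "class": classify_feature(fit, lo, hi, alpha=alpha),
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def classification_report(fits: pd.DataFrame) -> dict:
    """Tally of C/R/I labels plus the per-feature table."""
    tally = {c: int((fits["class"] == c).sum()) for c in (CLASS_CAUSAL, CLASS_REACTIVE, CLASS_INDETERMINATE)} if len(fits) else {CLASS_CAUSAL: 0, CLASS_REACTIVE: 0, CLASS_INDETERMINATE: 0}
    return {"n_features": int(len(fits)), "tally": tally, "table": fits}


def plot_data(
    norm_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    feature_id: str,
    n_grid: int = 50,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Scatter + fit-line + confidence-band data for external plotting."""
    logfc, ttd = pair_log_fold_change(norm_matrix.loc[[feature_id]], samples)
    tvals = ttd.to_numpy()
    fit = ttd_regress(tvals, logfc.loc[feature_id].to_numpy(), feature_id=feature_id)
    grid = np.linspace(tvals.min(), tvals.max(), n_grid)
    lo, hi = fit.confidence_band(grid, level=1.0 - alpha)
    scatter = pd.DataFrame(
        {
            "kind": "point",
            "ttd_years": tvals,
            "value": logfc.loc[feature_id].to_numpy(),
            "lower": np.nan,
            "upper": np.nan,
        }
    )
    line = pd.DataFrame(
        {
            "kind": "fit",
            "ttd_years": grid,
            "value": fit.predict(grid),
            "lower": lo,
            "upper": hi,
        }
    )
    out = pd.concat([scatter, line], ignore_index=True)
    out.insert(0, "feature_id", feature_id)
    return out
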