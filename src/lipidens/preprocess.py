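"""Feature filtering and normalization.

Order of operations in the pipeline:

1. blank filter — drop features whose mean study intensity is less than
   ``min_fold`` (default 1.5) times the mean reagent-blank intensity;
2. QC CV filter — drop features whose coefficient of variation over
   pooled-QC injections exceeds ``max_cv`` (default 30%);
3. natural-log transform (zeros replaced by half the smallest positive
   intensity in the matrix);
4. per-feature OLS removal of gel-status and batch effects
   (``log Y = b0 + b1*gel + b2*batch + e``, reference levels gel=0 and
   batch=1; the estimated gel/batch terms are subtracted);
5. upper-quantile scaling — every sample's 75th log-intensity
   percentile is shifted to the common grand mean.

Filters work on the natural (unlogged) intensity scale.  Boundary
semantics are inclusive on the passing side: a blank fold-change of
exactly ``min_fold`` passes, a CV of exactly ``max_cv`` passes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import ROLE_BLANK, ROLE_QC, ROLE_STUDY, FeatureTable


@dataclass
class FilterReport:
    """Per-feature filter diagnostics; one row per input feature."""

    table: pd.DataFrame  # columns: metric value(s), passed, reason

    @property
    def kept_ids(self) -> pd.Index:
        return self.table.index[self.table["passed"]]

    @property
    def n_dropped(self) -> int:
        return int((~self.table["passed"]).sum())


@dataclass
class NormalizationFit:
    """Per-feature gel/batch OLS estimates and the adjusted matrix."""

    coefficients: pd.DataFrame  # columns intercept, gel, batch (NaN if dropped)
    adjusted: pd.DataFrame  # normalized log intensities, features x samples
    dropped_terms: tuple[str, ...] = ()


def blank_filter(
    table: FeatureTable, min_fold: float = 1.5, study_only: bool = True
) -> tuple[FeatureTable, FilterReport]:
    """Retain features at least ``min_fold`` above mean blank signal.

    A blank mean of exactly zero counts as an infinite fold-change and
    passes.  ``study_only`` restricts the numerator to study samples
    (QC/blank injections excluded).
    """
    blank_ids = table.samples_with_role(ROLE_BLANK)
    if not blank_ids:
        raise ValueError("no blank samples present")
    num_ids = table.samples_with_role(ROLE_STUDY) if study_only else [
        s for s in table.sample_ids if s not in blank_ids
    ]
    mean_study = table.intensities[num_ids].mean(axis=1)
    mean_blank = table.intensities[blank_ids].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_study / mean_blank
    fold = fold.where(mean_blank > 0, np.inf)
    passed = fold >= min_fold
    report = FilterReport(
        pd.DataFrame(
            {
                "blank_fold": fold,
                "passed": passed,
                "reason": np.where(passed, "", f"blank_fold<{min_fold}"),
            },
            index=table.feature_ids,
        )
    )
    return table.subset(report.kept_ids), report


def qc_cv_filter(
    table: FeatureTable, max_cv: float = 0.30
) -> tuple[FeatureTable, FilterReport]:
    """Retain features whose QC coefficient of variation is <= ``max_cv``.

    CV = sample standard deviation (n-1 denominator) / mean, computed on
    the natural intensity scale over QC injections.  Features with a QC
    mean of zero are flagged and dropped.
    """
    qc_ids = table.samples_with_role(ROLE_QC)
    if len(qc_ids) < 2:
        raise ValueError("need at least 2 QC samples")
    qc = table.intensities[qc_ids]
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    zero_mean = mean == 0
    passed = (~zero_mean) & (cv <= max_cv)
    reason = np.where(zero_mean, "qc_mean_zero", np.where(passed, "", f"qc_cv>{max_cv}"))
    report = FilterReport(
        pd.DataFrame(
            {"qc_cv": cv.where(~zero_mean), "passed": passed, "reason": reason},
            index=table.feature_ids,
        )
    )
    return table.subset(report.kept_ids), report


def log_intensities(matrix: pd.DataFrame, pseudo: float | None = None) -> pd.DataFrame:
    """Natural-log transform with a half-minimum pseudo-value for zeros."""
    vals = matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative intensities cannot be log-transformed")
    if (vals == 0).any():
        if pseudo is None:
            positive = vals[vals > 0]
            if positive.size == 0:
                raise ValueError("all-zero intensity matrix")
            pseudo = 0.5 * positive.min()
        vals = np.where(vals == 0, pseudo, vals)
    return pd.DataFrame(np.log(vals), index=matrix.index, columns=matrix.columns)


def batch_gel_adjust(log_matrix: pd.DataFrame, samples: pd.DataFrame) -> NormalizationFit:
    """Remove per-feature gel and batch effects by OLS.

    Fits ``log Y = b0 + b1*gel + b2*1[batch 2] + e`` independently for
    every feature and subtracts the estimated gel/batch terms.  A
    constant gel or batch column is dropped with a warning (nothing to
    adjust); a collinear gel/batch pair is a singular design and raises.
    """
    sample_ids = log_matrix.columns
    meta = samples.loc[sample_ids]
    gel = meta["gel"].to_numpy(dtype=float)
    batch2 = (meta["batch"].to_numpy() == 2).astype(float)

    terms: list[tuple[str, np.ndarray]] = [("intercept", np.ones(len(sample_ids)))]
    dropped = []
    for name, col in (("gel", gel), ("batch", batch2)):
        if np.ptp(col) == 0:
            dropped.append(name)
            warnings.warn(f"{name} is constant across samples; term dropped", stacklevel=2)
        else:
            terms.append((name, col))
    X = np.column_stack([c for _, c in terms])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular gel/batch design (confounded covariates)")

    Y = log_matrix.to_numpy(dtype=float)  # features x samples
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # terms x features
    names = [n for n, _ in terms]
    coef = pd.DataFrame(beta.T, index=log_matrix.index, columns=names)
    for name in dropped:
        coef[name] = np.nan
    coef = coef.reindex(columns=["intercept", "gel", "batch"])

    adjust = np.zeros_like(Y)
    for name, col in (("gel", gel), ("batch", batch2)):
        if name not in dropped:
            adjust += np.outer(coef[name].to_numpy(), col)
    adjusted = pd.DataFrame(Y - adjust, index=log_matrix.index, columns=sample_ids)
    return NormalizationFit(coefficients=coef, adjusted=adjusted, dropped_terms=tuple(dropped))


def upper_quantile_scale(log_matrix: pd.DataFrame, q: float = 75.0) -> pd.DataFrame:
    """Equalize each sample's ``q``-th log-intensity percentile.

    Per sample, subtract its percentile (linear interpolation between
    order statistics) and add the grand mean of all samples'
    percentiles, so every sample ends at the same upper quantile.
    """
    if log_matrix.shape[0] < 1:
        raise ValueError("need at least one feature")
    q75 = np.percentile(log_matrix.to_numpy(dtype=float), q, axis=0)
    target = q75.mean()
    return log_matrix - q75 + target


def normalize(
    table: FeatureTable, samples: pd.DataFrame, pseudo: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, NormalizationFit]:
    """log-transform + gel/batch adjust + upper-quantile scale.

    Operates on study samples only.  Returns ``(raw_log, normalized,
    fit)`` where ``raw_log`` is the unadjusted log matrix used by the
    case-control linear model.
    """
    study_ids = table.samples_with_role(ROLE_STUDY)
    raw_log = log_intensities(table.intensities[study_ids], pseudo=pseudo)
    fit = batch_gel_adjust(raw_log, samples)
    normalized = upper_quantile_scale(fit.adjusted)
    return raw_log, normalized, fit
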