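"""Ensemble variable selection.

A feature enters the final selected set only if it passes all three
criteria:

1. its case-control linear-model p-value ranks in the top ``top_frac``
   (default 1%) of features,
2. it is retained by bootstrap-LASSO stability selection (selection
   frequency >= ``freq_cut``, default 10%, over B bootstrap replicates
   along a descending penalty grid),
3. its random-forest permutation importance ranks in the top
   ``top_frac`` of features,

and it is not on the exclusion list (the stand-in for manual
peak-morphology review).

The linear model runs on the raw (pre-adjustment) log intensities with
gel, batch, age and gender as covariates; the LASSO and forest run on
the normalized (gel/batch-adjusted, upper-quantile-scaled) matrix with
age and gender appended as ordinary penalized candidates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from ._lasso import logistic_lambda_max, logistic_lasso_path, standardize_columns

#: names of the demographic covariates carried alongside features in the
#: penalized and forest models
COVARIATE_ROWS = ("age", "gender")


# ---------------------------------------------------------------------------
# criterion 1: per-feature linear model
# ---------------------------------------------------------------------------

@dataclass
class CaseControlModelFit:
    """Per-feature case-control OLS results.

    ``table`` columns: beta_caco, se, t, p_value, p_rank, q_value,
    fold_change (exp of the mean paired log fold-change).
    """

    table: pd.DataFrame
    n_samples: int
    dof: int
    covariates: tuple[str, ...]

    @property
    def feature_ids(self) -> pd.Index:
        return self.table.index


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def paired_log_fold_change_means(log_matrix: pd.DataFrame, samples: pd.DataFrame) -> pd.Series:
    """exp(mean over pairs of log(case) - log(control)) per feature."""
    study = samples.loc[log_matrix.columns]
    cases = study[study["caco"] == "case"].sort_values("pair_id")
    ctrls = study[study["caco"] == "control"].sort_values("pair_id")
    if not (cases["pair_id"].to_numpy() == ctrls["pair_id"].to_numpy()).all():
        raise ValueError("incomplete case-control pairs")
    diff = log_matrix[cases.index].to_numpy() - log_matrix[ctrls.index].to_numpy()
    return pd.Series(np.exp(diff.mean(axis=1)), index=log_matrix.index, name="fold_change")


def fit_case_control_lm(
    log_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: Iterable[str] = ("gel", "batch", "age", "gender"),
) -> CaseControlModelFit:
    """OLS of log intensity on case-control status plus covariates.

    Fits every feature with a shared design matrix in one pass and
    reports the two-sided t-test p-value for the case-control
    coefficient.  Constant covariate columns are dropped with a
    warning.  Features are ranked ascending by p-value (ties share the
    lowest rank).
    """
    meta = samples.loc[log_matrix.columns]
    if not (meta["role"] == "study").all():
        raise ValueError("case-control model expects study samples only")
    caco = (meta["caco"].to_numpy() == "case").astype(float)
    if np.ptp(caco) == 0:
        raise ValueError("case-control status is constant")

    encoders = {
        "gel": lambda m: m["gel"].to_numpy(dtype=float),
        "batch": lambda m: (m["batch"].to_numpy() == 2).astype(float),
        "age": lambda m: m["age"].to_numpy(dtype=float),
        "gender": lambda m: (m["gender"].to_numpy() == "M").astype(float),
    }
    cols = [("intercept", np.ones(len(meta))), ("caco", caco)]
    used = ["intercept", "caco"]
    for name in covariates:
        col = encoders[name](meta) if name in encoders else meta[name].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped", stacklevel=2)
            continue
        cols.append((name, col))
        used.append(name)
    X = np.column_stack([c for _, c in cols])
    n, k = X.shape
    if n <= k:
        raise ValueError(f"too few samples ({n}) for {k} model terms")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise ValueError("collinear design matrix in case-control model")

    Y = log_matrix.to_numpy(dtype=float).T  # samples x features
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # k x p
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta[1] / se
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    pval = np.where(se == 0, 1.0, pval)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "beta_caco": beta[1],
            "se": se,
            "t": tval,
            "p_value": pval,
        },
        index=log_matrix.index,
    )
    table["p_rank"] = table["p_value"].rank(method="min").astype(int)
    table["q_value"] = _benjamini_hochberg(pval)
    table["fold_change"] = paired_log_fold_change_means(log_matrix, samples)
    return CaseControlModelFit(table=table, n_samples=n, dof=dof, covariates=tuple(used[2:]))


# ---------------------------------------------------------------------------
# criterion 2: bootstrap-LASSO stability selection
# ---------------------------------------------------------------------------

@dataclass
class StabilityProfile:
    """Selection frequencies over the penalty grid.

    ``frequencies`` has one row per feature (plus the ``age``/``gender``
    covariate rows) and one column per penalty, descending.  The summary
    frequency is the per-feature maximum over the middle portion of the
    grid (the extremes, where selection is vacuous or saturated, are
    excluded); a feature is retained when its summary is >= ``freq_cut``.
    """

    penalties: np.ndarray
    frequencies: pd.DataFrame
    summary: pd.Series
    retained: pd.Series  # features only (bool)
    freq_cut: float
    window: tuple[int, int]  # [start, stop) grid indices entering the summary
    n_boot: int

    @property
    def feature_summary(self) -> pd.Series:
        return self.summary.drop(index=list(COVARIATE_ROWS), errors="ignore")


def default_penalty_grid(
    X: np.ndarray, y: np.ndarray, size: int = 50, min_ratio: float = 1e-3
) -> np.ndarray:
    """Log-spaced grid from the data-derived maximal penalty downwards."""
    lam_max = logistic_lambda_max(standardize_columns(X), y)
    return np.geomspace(lam_max, lam_max * min_ratio, size)


def bootstrap_lasso(
    norm_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    B: int = 500,
    grid: np.ndarray | None = None,
    grid_size: int = 50,
    freq_cut: float = 0.10,
    seed: int | None = None,
    resample_unit: str = "pair",
    window_trim: float = 0.10,
) -> StabilityProfile:
    """Stability selection via bootstrapped L1 logistic regression.

    Case-control status is regressed on the normalized log intensities
    of all features plus age and gender (penalized like any feature).
    Each bootstrap replicate resamples matched pairs with replacement
    (``resample_unit='subject'`` resamples individual samples instead;
    single-class replicates are then redrawn).  The full L1 path is fit
    per replicate along the shared descending grid, and nonzero
    coefficients are counted per (feature, penalty).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if resample_unit not in ("pair", "subject"):
        raise ValueError("resample_unit must be 'pair' or 'subject'")
    meta = samples.loc[norm_matrix.columns]
    y_full = (meta["caco"].to_numpy() == "case").astype(float)
    age = meta["age"].to_numpy(dtype=float)
    gender = (meta["gender"].to_numpy() == "M").astype(float)
    X_full = np.column_stack([norm_matrix.to_numpy(dtype=float).T, age, gender])
    n, p_all = X_full.shape
    row_names = list(norm_matrix.index) + list(COVARIATE_ROWS)

    if grid is None:
        grid = default_penalty_grid(X_full, y_full, size=grid_size)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1 or np.any(grid <= 0) or np.any(np.diff(grid) > 0):
        raise ValueError("penalty grid must be positive and descending")

    pair_ids = meta["pair_id"].to_numpy()
    uniq_pairs = np.unique(pair_ids)
    pair_rows = {pid: np.flatnonzero(pair_ids == pid) for pid in uniq_pairs}

    rng = np.random.default_rng(seed)
    counts = np.zeros((p_all, grid.size))
    for _ in range(B):
        for _redraw in range(1000):
            if resample_unit == "pair":
                chosen = rng.choice(uniq_pairs, size=uniq_pairs.size, replace=True)
                rows = np.concatenate([pair_rows[pid] for pid in chosen])
            else:
                rows = rng.integers(0, n, size=n)
            yb = y_full[rows]
            if 0.0 < yb.mean() < 1.0:
                break
        else:  # pragma: no cover - pair resampling always has both classes
            raise RuntimeError("could not draw a two-class bootstrap replicate")
        Xb = standardize_columns(X_full[rows])
        coefs, _ = logistic_lasso_path(Xb, yb, grid)
        counts += coefs != 0.0

    freq = pd.DataFrame(counts / B, index=row_names, columns=np.arange(grid.size))
    lo = int(math.floor(window_trim * grid.size))
    hi = int(grid.size - lo)
    if hi <= lo:  # degenerate tiny grids: use everything
        lo, hi = 0, grid.size
    summary = freq.iloc[:, lo:hi].max(axis=1)
    feature_summary = summary.loc[norm_matrix.index]
    retained = feature_summary >= freq_cut
    return StabilityProfile(
        penalties=grid,
        frequencies=freq,
        summary=summary,
        retained=retained,
        freq_cut=freq_cut,
        window=(lo, hi),
        n_boot=B,
    )


def choose_freq_cut(
    profile: StabilityProfile,
    ceiling: float = 0.95,
    min_gap: float = 0.05,
    fallback: float = 0.10,
) -> float:
    """Data-driven stability cutoff at the largest frequency gap.

    Sorts summary frequencies descending and places the cutoff in the
    middle of the widest consecutive gap whose upper edge is below
    ``ceiling``; falls back to the fixed default when no gap is at
    least ``min_gap`` wide.
    """
    freqs = np.sort(profile.feature_summary.to_numpy())[::-1]
    if freqs.size < 2:
        return fallback
    best_gap, best_cut = 0.0, None
    for upper, lower in zip(freqs[:-1], freqs[1:]):
        gap = upper - lower
        cut = 0.5 * (upper + lower)
        if cut <= ceiling and gap > best_gap:
            best_gap = gap
            best_cut = cut
    if best_cut is None or best_gap < min_gap:
        return fallback
    return float(best_cut)


# ---------------------------------------------------------------------------
# criterion 3: random-forest importance
# ---------------------------------------------------------------------------

def rf_importance(
    norm_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    n_trees: int = 500,
    seed: int | None = None,
    importance: str = "permutation",
) -> pd.Series:
    """Out-of-bag permutation importance from a bagged classification forest.

    Builds ``n_trees`` bootstrap trees (``max_features='sqrt'``) for the
    case-control outcome on the same covariate set as the LASSO
    (features + age + gender).  Importance of a variable is the mean
    over trees of the drop in out-of-bag accuracy after permuting that
    variable among the tree's out-of-bag samples (variables unused by a
    tree contribute zero).  ``importance='impurity'`` averages the
    trees' impurity importances instead.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if importance not in ("permutation", "impurity"):
        raise ValueError("importance must be 'permutation' or 'impurity'")
    meta = samples.loc[norm_matrix.columns]
    y = (meta["caco"].to_numpy() == "case").astype(int)
    age = meta["age"].to_numpy(dtype=float)
    gender = (meta["gender"].to_numpy() == "M").astype(float)
    X = np.column_stack([norm_matrix.to_numpy(dtype=float).T, age, gender])
    n, p_all = X.shape
    row_names = list(norm_matrix.index) + list(COVARIATE_ROWS)

    rng = np.random.default_rng(seed)
    imp = np.zeros(p_all)
    all_rows = np.arange(n)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(all_rows, boot, assume_unique=False)
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        if importance == "impurity":
            imp += tree.feature_importances_
            continue
        if oob.size == 0:  # pragma: no cover - vanishing probability
            continue
        Xo = X[oob].copy()
        yo = y[oob]
        acc = float(np.mean(tree.predict(Xo) == yo))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for j in used:
            saved = Xo[:, j].copy()
            Xo[:, j] = saved[rng.permutation(oob.size)]
            acc_perm = float(np.mean(tree.predict(Xo) == yo))
            Xo[:, j] = saved
            imp[j] += acc - acc_perm
    imp /= n_trees
    return pd.Series(imp, index=row_names, name="rf_importance")


# ---------------------------------------------------------------------------
# intersection + exclusion loop
# ---------------------------------------------------------------------------

@dataclass
class SelectionProfile:
    """Merged evidence and final selection flags, one row per feature."""

    table: pd.DataFrame
    top_frac: float
    n_top: int
    iterations: int = 1

    @property
    def selected_features(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def intersect_criteria(
    fit: CaseControlModelFit,
    profile: StabilityProfile,
    importance: pd.Series,
    top_frac: float = 0.01,
    exclusions: Iterable[str] = (),
) -> SelectionProfile:
    """Select features passing all three criteria and not excluded.

    The rank cutoff is ``ceil(top_frac * p)`` with ties at the boundary
    admitted (min-rank convention).
    """
    feats = fit.feature_ids
    if set(feats) != set(profile.retained.index):
        raise ValueError("feature sets of linear model and stability profile differ")
    imp_feats = importance.drop(index=list(COVARIATE_ROWS), errors="ignore")
    if set(feats) != set(imp_feats.index):
        raise ValueError("feature sets of linear model and importance differ")

    p = len(feats)
    n_top = max(1, math.ceil(top_frac * p))
    table = fit.table.copy()
    table["stability_freq"] = profile.feature_summary.reindex(feats)
    table["rf_importance"] = imp_feats.reindex(feats)
    table["rf_rank"] = table["rf_importance"].rank(method="min", ascending=False).astype(int)
    table["pass_lm"] = table["p_rank"] <= n_top
    table["pass_lasso"] = profile.retained.reindex(feats)
    table["pass_rf"] = table["rf_rank"] <= n_top
    excl = set(exclusions)
    table["excluded"] = [f in excl for f in feats]
    table["selected"] = (
        table["pass_lm"] & table["pass_lasso"] & table["pass_rf"] & ~table["excluded"]
    )
    return SelectionProfile(table=table, top_frac=top_frac, n_top=n_top)


def selection_loop(
    run: Callable[[frozenset], SelectionProfile],
    morphology_flags: Iterable[str],
    max_iterations: int = 100,
) -> SelectionProfile:
    """Re-run selection until no flagged feature remains selected.

    ``run`` maps a (frozen) exclusion set to a fresh
    :class:`SelectionProfile`; flagged features that show up in the
    selected set are added to the exclusions and selection repeats.
    Terminates because the exclusion set grows monotonically.
    """
    flags = set(morphology_flags)
    exclusions: set[str] = set()
    for it in range(1, max_iterations + 1):
        profile = run(frozenset(exclusions))
        bad = set(profile.selected_features) & flags
        if not bad:
            profile.iterations = it
            return profile
        exclusions |= bad
    raise RuntimeError("selection loop failed to converge")  # pragma: no cover
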