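"""Pipeline orchestration and reporting.

``run_pipeline`` wires the stages together — blank/QC filtering,
normalization, ensemble selection, time-to-diagnosis classification,
cohort descriptives and in-sample classification rates — and writes a
deterministic TSV/JSON report bundle.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from . import __version__
from .ensemble import (
    bootstrap_lasso,
    choose_freq_cut,
    fit_case_control_lm,
    intersect_criteria,
    rf_importance,
    selection_loop,
)
from .preprocess import blank_filter, normalize, qc_cv_filter
from .tables import FeatureTable, read_tables, study_samples
from .ttd import classification_report, classify_features

log = logging.getLogger("lipidens")


# ---------------------------------------------------------------------------
# cohort descriptives
# ---------------------------------------------------------------------------

def cohort_table(samples: pd.DataFrame, covariates: list[str] | None = None) -> pd.DataFrame:
    """Case/control descriptive statistics with nominal test p-values.

    Continuous covariates get median/min/max per group and a two-sided
    Wilcoxon rank-sum (Mann-Whitney) p-value; categorical covariates get
    level counts and a Pearson chi-square p-value.  Degenerate
    covariates (a single value overall) are reported with an NA p-value
    and a warning.
    """
    study = study_samples(samples)
    if covariates is None:
        covariates = ["age", "gender", "ttd_years"]
    missing = [c for c in covariates if c not in study.columns]
    if missing:
        raise KeyError(f"covariates not in sample frame: {missing}")
    cases = study[study["caco"] == "case"]
    ctrls = study[study["caco"] == "control"]
    rows = []
    for cov in covariates:
        col = study[cov]
        numeric = pd.api.types.is_numeric_dtype(col)
        a, b = cases[cov].dropna(), ctrls[cov].dropna()
        if col.dropna().nunique() <= 1:
            warnings.warn(f"covariate {cov!r} is constant; test skipped", stacklevel=2)
            pval, test = np.nan, "none"
            stats_case = stats_ctrl = f"n={len(a)}" if not numeric else ""
        elif numeric:
            pval = float(
                stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
            )
            test = "wilcoxon_rank_sum"
            stats_case = f"{a.median():g} [{a.min():g}, {a.max():g}]"
            stats_ctrl = f"{b.median():g} [{b.min():g}, {b.max():g}]"
        else:
            levels = sorted(col.dropna().unique())
            counts = np.array(
                [[int((a == lv).sum()) for lv in levels], [int((b == lv).sum()) for lv in levels]]
            )
            keep = counts.sum(axis=0) > 0
            chi2, pval, _, _ = stats.chi2_contingency(counts[:, keep], correction=False)
            pval = float(pval)
            test = "chi_square"
            stats_case = "; ".join(f"{lv}:{n}" for lv, n in zip(levels, counts[0]))
            stats_ctrl = "; ".join(f"{lv}:{n}" for lv, n in zip(levels, counts[1]))
        rows.append(
            {
                "covariate": cov,
                "type": "continuous" if numeric else "categorical",
                "cases": stats_case,
                "controls": stats_ctrl,
                "test": test,
                "p_value": pval,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# volcano export
# ---------------------------------------------------------------------------

def volcano_export(fit, selected: list[str] | None = None) -> pd.DataFrame:
    """Fold-change vs -log10 p table (reference line at p = 0.05)."""
    selected = set(selected or [])
    out = pd.DataFrame(
        {
            "fold_change": fit.table["fold_change"],
            "p_value": fit.table["p_value"],
            "minus_log10_p": -np.log10(fit.table["p_value"]),
            "selected": [f in selected for f in fit.table.index],
        },
        index=fit.table.index,
    )
    out.attrs["reference_p"] = 0.05
    return out


# ---------------------------------------------------------------------------
# in-sample classification rate
# ---------------------------------------------------------------------------

@dataclass
class InSampleResult:
    """Learning-set classification rate (optimistic by construction)."""

    rate: float
    n_samples: int
    n_features: int
    penalized_fallback: bool
    note: str = "in-sample rate; optimistic because selection and evaluation share the data"


def in_sample_classification(
    norm_matrix: pd.DataFrame, samples: pd.DataFrame, feature_ids: list[str]
) -> InSampleResult:
    """Fit logistic regression on the named features and score the same data.

    Near-separable fits fall back to a ridge-penalized model (flagged).
    The rate is the fraction of correct calls at the 0.5 threshold.
    """
    if not feature_ids:
        raise ValueError("empty feature set")
    meta = samples.loc[norm_matrix.columns]
    y = (meta["caco"].to_numpy() == "case").astype(int)
    X = norm_matrix.loc[list(feature_ids)].to_numpy(dtype=float).T
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf = LogisticRegression(C=1e6, max_iter=1000).fit(X, y)
        except ConvergenceWarning:
            fallback = True
            clf = LogisticRegression(C=1.0, max_iter=5000).fit(X, y)
    rate = float(np.mean(clf.predict(X) == y))
    return InSampleResult(
        rate=rate, n_samples=len(y), n_features=len(feature_ids), penalized_fallback=fallback
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Knobs of the end-to-end run (all stochastic stages use ``seed``)."""

    features_path: str | None = None
    samples_path: str | None = None
    out_dir: str = "results"
    min_fold: float = 1.5
    max_cv: float = 0.30
    boot: int = 500
    grid_size: int = 50
    freq_cut: float = 0.10
    auto_freq_cut: bool = False
    top_frac: float = 0.01
    n_trees: int = 500
    alpha: float = 0.05
    seed: int = 0
    exclusions_path: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.top_frac <= 1):
            raise ValueError("top_frac must lie in (0, 1]")
        if not (0 <= self.freq_cut <= 1):
            raise ValueError("freq_cut must lie in [0, 1]")
        if self.min_fold < 0 or self.max_cv < 0:
            raise ValueError("filter thresholds must be >= 0")
        if self.boot < 1 or self.grid_size < 1 or self.n_trees < 1:
            raise ValueError("boot, grid_size and n_trees must be >= 1")


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{sig}g}")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return _round_sig(float(o))
    if isinstance(o, float):
        return _round_sig(o)
    raise TypeError(f"not serializable: {type(o)}")


def run_pipeline(
    config: PipelineConfig,
    table: FeatureTable | None = None,
    samples: pd.DataFrame | None = None,
    morphology_flags: list[str] | None = None,
) -> dict:
    """Execute filter -> normalize -> select -> classify -> report.

    Inputs come either from ``config.features_path``/``samples_path`` or
    as in-memory objects.  Writes the TSV/JSON bundle under
    ``config.out_dir`` and returns the report dictionary.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if table is None or samples is None:
        if not (config.features_path and config.samples_path):
            raise ValueError("need features/samples paths or in-memory tables")
        table, samples = read_tables(config.features_path, config.samples_path)
    flags = list(morphology_flags or [])
    if config.exclusions_path:
        flags += [
            line.strip()
            for line in Path(config.exclusions_path).read_text().splitlines()
            if line.strip()
        ]

    counts = {"input": table.n_features}
    log.info("lipidens %s | seed=%d | %d features in", __version__, config.seed, table.n_features)

    # stage 1-2: filters
    table_b, rep_blank = blank_filter(table, min_fold=config.min_fold)
    counts["after_blank_filter"] = table_b.n_features
    table_q, rep_qc = qc_cv_filter(table_b, max_cv=config.max_cv)
    counts["after_qc_cv_filter"] = table_q.n_features
    filter_report = rep_blank.table.join(rep_qc.table, how="left", rsuffix="_qc")
    filter_report["passed"] = filter_report["passed"].fillna(False) & filter_report[
        "passed_qc"
    ].fillna(False)
    filter_report["reason"] = (
        filter_report["reason"].fillna("").astype(str)
        + filter_report["reason_qc"].fillna("").astype(str)
    )
    filter_report = filter_report[["blank_fold", "qc_cv", "passed", "reason"]]
    filter_report.index.name = "feature_id"
    filter_report.to_csv(out_dir / "filter_report.tsv", sep="\t")
    log.info("filters: %d -> %d -> %d features", counts["input"],
             counts["after_blank_filter"], counts["after_qc_cv_filter"])

    report: dict = {
        "schema_version": 1,
        "package_version": __version__,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("features_path", "samples_path", "out_dir")
        },
        "stage_counts": counts,
    }
    if table_q.n_features == 0:
        report["selected_features"] = []
        report["ttd_classes"] = {}
        report["note"] = "no features survived filtering"
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=_json_default) + "\n")
        return report

    # stage 3: normalization
    raw_log, norm, fit_norm = normalize(table_q, samples)
    norm_out = norm.copy()
    norm_out.index.name = "feature_id"
    norm_out.to_csv(out_dir / "normalized.tsv", sep="\t")

    # stage 4: ensemble selection (with the morphology exclusion loop)
    def run_selection(exclusions: frozenset):
        keep = [f for f in norm.index if f not in exclusions]
        lm = fit_case_control_lm(raw_log.loc[keep], samples)
        stab = bootstrap_lasso(
            norm.loc[keep],
            samples,
            B=config.boot,
            grid_size=config.grid_size,
            freq_cut=config.freq_cut,
            seed=config.seed,
        )
        if config.auto_freq_cut:
            cut = choose_freq_cut(stab)
            stab.retained = stab.feature_summary >= cut
            stab.freq_cut = cut
        imp = rf_importance(norm.loc[keep], samples, n_trees=config.n_trees, seed=config.seed)
        return intersect_criteria(lm, stab, imp, top_frac=config.top_frac)

    profile = selection_loop(run_selection, flags)
    sel_table = profile.table.copy()
    sel_table.index.name = "feature_id"
    sel_table.to_csv(out_dir / "selection.tsv", sep="\t")
    selected = profile.selected_features
    counts["selected"] = len(selected)
    log.info("ensemble selection: %d features selected (%d loop iterations)",
             len(selected), profile.iterations)

    # stage 5: volcano + ttd classification
    lm_full = fit_case_control_lm(raw_log, samples)
    volcano = volcano_export(lm_full, selected=selected)
    volcano.index.name = "feature_id"
    volcano.to_csv(out_dir / "volcano.tsv", sep="\t")

    classes = pd.DataFrame(columns=["intercept", "slope", "slope_se", "slope_p", "class"])
    if selected:
        classes = classify_features(norm, samples, feature_ids=selected, alpha=config.alpha)
    classes.index.name = "feature_id"
    classes.to_csv(out_dir / "ttd_classes.tsv", sep="\t")
    cls_report = classification_report(classes)

    # stage 6: cohort descriptives + in-sample rates
    desc = cohort_table(samples)
    desc.to_csv(out_dir / "cohort_table.tsv", sep="\t")

    rates = {}
    if selected:
        rates["selected"] = asdict(in_sample_classification(norm, samples, selected))
        causal = list(classes.index[classes["class"] == "C"])
        if causal:
            rates["causal_only"] = asdict(in_sample_classification(norm, samples, causal))

    report.update(
        {
            "stage_counts": counts,
            "selection_iterations": profile.iterations,
            "selected_features": selected,
            "ttd_classes": {f: str(c) for f, c in classes["class"].items()},
            "class_tally": cls_report["tally"],
            "in_sample_rates": rates,
        }
    )
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=_json_default) + "\n")
    return report
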