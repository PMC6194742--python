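"""Synthetic matched case-control cohorts with planted effects.

Generates feature tables whose statistical structure matches what the
downstream analysis assumes: log-normal feature intensities, a
two-batch layout with a gel-status artifact confined to batch 1, pooled
QC injections, reagent blanks, and per-feature case-control effects
that are constant in time-to-diagnosis ("causal"), decay linearly to
zero with time-to-diagnosis ("reactive"), grow with time-to-diagnosis
("indeterminate"), or are absent ("null").

The generating model for the log intensity of feature k in study
subject i is::

    base_k + batchShift_k * 1[batch 2] + gelShift_k * 1[gel]
           + (s/2) * logFC_k(ttd_i) + eps,   s = +1 cases, -1 controls

with ``eps ~ Normal(0, residual_sd)``.  Members of a pair share age,
gender, batch and (for bookkeeping) the case's time to diagnosis.
Everything is drawn from one seeded generator, so identical inputs give
identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import (
    ROLE_BLANK,
    ROLE_QC,
    ROLE_STUDY,
    FeatureTable,
    read_samples,
    read_feature_table,
    write_feature_table,
    write_samples,
)

EFFECT_TYPES = ("causal", "reactive", "indeterminate", "null")


@dataclass(frozen=True)
class PlantedEffect:
    """A per-feature case-control effect planted into the cohort.

    ``beta0`` is the log-fold-change at ttd = 0 (natural-log units).
    Reactive effects shrink linearly to zero over ``decay_span`` years;
    indeterminate effects grow in magnitude by ``growth_rate`` per year.
    """

    feature_index: int
    effect_type: str
    beta0: float = 0.0
    decay_span: float = math.inf
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.effect_type not in EFFECT_TYPES:
            raise ValueError(f"unknown effect type {self.effect_type!r}")
        if self.effect_type == "null" and self.beta0 != 0.0:
            raise ValueError("null effects must have beta0 = 0")
        if self.effect_type == "reactive" and not self.decay_span > 0:
            raise ValueError("reactive effects need decay_span > 0")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")
        for v in (self.beta0, self.decay_span, self.growth_rate):
            if math.isnan(v):
                raise ValueError("non-finite effect parameter")

    def log_fold_change(self, ttd: float | np.ndarray) -> np.ndarray:
        """Planted log fold-change (case minus control) at the given ttd."""
        ttd = np.asarray(ttd, dtype=float)
        if self.effect_type == "causal":
            return np.full_like(ttd, self.beta0)
        if self.effect_type == "reactive":
            return self.beta0 * np.maximum(0.0, 1.0 - ttd / self.decay_span)
        if self.effect_type == "indeterminate":
            sign = 1.0 if self.beta0 >= 0 else -1.0
            return self.beta0 + sign * self.growth_rate * ttd
        return np.zeros_like(ttd)


@dataclass
class CohortDesign:
    """Cohort layout: pair count, batches, gel artifact, QC and blanks."""

    n_pairs: int = 66
    p_features: int = 2000
    batch1_fraction: float = 48 / 66  # fraction of pairs run in batch 1
    gel_probability: float = 0.46  # per-sample gel probability inside batch 1
    age_range: tuple[int, int] = (35, 65)
    male_fraction: float = 51 / 66
    ttd_range: tuple[float, float] = (0.1, 14.4)
    n_qc: int = 13
    n_blank: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.p_features < 1:
            raise ValueError("p_features must be >= 1")
        if not 0.0 <= self.batch1_fraction <= 1.0:
            raise ValueError("batch1_fraction must lie in [0, 1]")
        if not 0.0 <= self.gel_probability <= 1.0:
            raise ValueError("gel_probability must lie in [0, 1]")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")
        if self.ttd_range[0] <= 0 or self.ttd_range[1] < self.ttd_range[0]:
            raise ValueError("ttd_range must be positive and ordered")
        if self.n_blank < 0 or self.n_qc < 0:
            raise ValueError("n_qc / n_blank must be >= 0")


@dataclass
class NoiseModel:
    """Nuisance-variation parameters of the generator."""

    base_log_mean_range: tuple[float, float] = (4.0, 10.0)
    residual_sd: float = 0.5
    qc_cv_range: tuple[float, float] = (0.05, 0.15)
    blank_fraction_range: tuple[float, float] = (0.0, 0.5)
    batch_shift_sd: float = 0.3
    gel_shift_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.residual_sd < 0 or self.batch_shift_sd < 0 or self.gel_shift_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        lo, hi = self.qc_cv_range
        if lo < 0 or hi < lo:
            raise ValueError("qc_cv_range must be ordered and >= 0")
        lo, hi = self.blank_fraction_range
        if lo < 0 or hi > 1.5 or hi < lo:
            raise ValueError("blank fractions must lie in [0, 1.5]")
        for v in (*self.base_log_mean_range, self.residual_sd):
            if not math.isfinite(v):
                raise ValueError("non-finite noise parameter")


def generate_cohort(
    design: CohortDesign,
    effects: list[PlantedEffect] | None = None,
    noise: NoiseModel | None = None,
) -> tuple[FeatureTable, pd.DataFrame, pd.DataFrame]:
    """Draw one cohort; returns (feature table, sample frame, truth table)."""
    effects = list(effects or [])
    noise = noise or NoiseModel()
    p, npairs = design.p_features, design.n_pairs
    by_index: dict[int, PlantedEffect] = {}
    for e in effects:
        if not 0 <= e.feature_index < p:
            raise ValueError(f"effect references feature index {e.feature_index} out of range")
        if e.feature_index in by_index:
            raise ValueError(f"duplicate effect for feature index {e.feature_index}")
        by_index[e.feature_index] = e

    rng = np.random.default_rng(design.seed)

    # ---- subjects ------------------------------------------------------
    ages = rng.integers(design.age_range[0], design.age_range[1] + 1, size=npairs)
    male = rng.random(npairs) < design.male_fraction
    ttd = rng.uniform(design.ttd_range[0], design.ttd_range[1], size=npairs)
    n_b1 = int(round(design.batch1_fraction * npairs))
    batch1 = np.zeros(npairs, dtype=bool)
    batch1[rng.permutation(npairs)[:n_b1]] = True
    batch = np.where(batch1, 1, 2)
    # per-sample gel indicator (batch 2 is always gel-free)
    gel_case = (rng.random(npairs) < design.gel_probability) & batch1
    gel_ctrl = (rng.random(npairs) < design.gel_probability) & batch1

    width = max(2, len(str(npairs)))
    pair_ids = [f"P{i + 1:0{width}d}" for i in range(npairs)]
    rows = []
    for i, pid in enumerate(pair_ids):
        for caco, gel in (("case", gel_case[i]), ("control", gel_ctrl[i])):
            rows.append(
                {
                    "sample_id": f"{pid}_{caco}",
                    "role": ROLE_STUDY,
                    "pair_id": pid,
                    "caco": caco,
                    "gel": int(gel),
                    "batch": int(batch[i]),
                    "age": int(ages[i]),
                    "gender": "M" if male[i] else "F",
                    "ttd_years": float(ttd[i]),
                }
            )
    # QC injections alternate batches proportionally to batch size
    qc_batches = []
    if design.n_qc:
        n_qc1 = int(round(design.n_qc * n_b1 / npairs)) if npairs else 0
        qc_batches = [1] * n_qc1 + [2] * (design.n_qc - n_qc1)
    for q, b in enumerate(qc_batches, start=1):
        rows.append(
            {
                "sample_id": f"QC{q:02d}",
                "role": ROLE_QC,
                "pair_id": "NA",
                "caco": "NA",
                "gel": 0,
                "batch": b,
                "age": 0,
                "gender": "NA",
                "ttd_years": 0.0,
            }
        )
    for bl in range(1, design.n_blank + 1):
        rows.append(
            {
                "sample_id": f"BLANK{bl:02d}",
                "role": ROLE_BLANK,
                "pair_id": "NA",
                "caco": "NA",
                "gel": 0,
                "batch": 1,
                "age": 0,
                "gender": "NA",
                "ttd_years": 0.0,
            }
        )
    samples = pd.DataFrame(rows).set_index("sample_id")

    # ---- per-feature parameters ---------------------------------------
    base = rng.uniform(*noise.base_log_mean_range, size=p)
    batch_shift = rng.normal(0.0, noise.batch_shift_sd, size=p) if noise.batch_shift_sd else np.zeros(p)
    gel_shift = rng.normal(0.0, noise.gel_shift_sd, size=p) if noise.gel_shift_sd else np.zeros(p)
    qc_cv = rng.uniform(*noise.qc_cv_range, size=p)
    blank_frac = rng.uniform(*noise.blank_fraction_range, size=p)

    # ---- study intensities --------------------------------------------
    study = samples[samples["role"] == ROLE_STUDY]
    n_study = len(study)
    sign = np.where(study["caco"].to_numpy() == "case", 1.0, -1.0)
    is_b2 = (study["batch"].to_numpy() == 2).astype(float)
    is_gel = study["gel"].to_numpy().astype(float)
    subj_ttd = study["ttd_years"].to_numpy()

    logm = (
        base[:, None]
        + np.outer(batch_shift, is_b2)
        + np.outer(gel_shift, is_gel)
    )
    for k, eff in by_index.items():
        logm[k] += 0.5 * sign * eff.log_fold_change(subj_ttd)
    if noise.residual_sd > 0:
        logm += rng.normal(0.0, noise.residual_sd, size=(p, n_study))
    study_nat = np.exp(logm)

    # ---- QC intensities: lognormal around the per-batch pooled mean ----
    qc_cols = {}
    qc_ids = samples.index[samples["role"] == ROLE_QC]
    for sid in qc_ids:
        b = samples.loc[sid, "batch"]
        in_batch = study["batch"].to_numpy() == b
        pooled = study_nat[:, in_batch].mean(axis=1) if in_batch.any() else study_nat.mean(axis=1)
        sigma = np.sqrt(np.log1p(qc_cv**2))
        draw = rng.normal(0.0, 1.0, size=p)
        qc_cols[sid] = pooled * np.exp(sigma * draw - 0.5 * sigma**2)

    # ---- blanks: fixed fraction of the mean study signal ---------------
    blank_ids = samples.index[samples["role"] == ROLE_BLANK]
    mean_study = study_nat.mean(axis=1)
    blank_cols = {sid: blank_frac * mean_study for sid in blank_ids}

    fwidth = max(4, len(str(p)))
    feature_ids = pd.Index([f"F{k + 1:0{fwidth}d}" for k in range(p)], name="feature_id")
    intensities = pd.DataFrame(study_nat, index=feature_ids, columns=study.index)
    for sid in qc_ids:
        intensities[sid] = qc_cols[sid]
    for sid in blank_ids:
        intensities[sid] = blank_cols[sid]
    intensities = intensities.rename_axis(columns=None)

    # invented but plausible mass/RT annotations (not used statistically)
    mz = np.sort(rng.uniform(150.0, 1000.0, size=p))
    rt = rng.uniform(30.0, 1300.0, size=p)
    features = pd.DataFrame({"mz": mz, "rt_sec": rt}, index=feature_ids)

    truth = pd.DataFrame(
        {
            "effect_type": "null",
            "beta0": 0.0,
            "decay_span": math.inf,
            "growth_rate": 0.0,
        },
        index=feature_ids,
    )
    for k, eff in by_index.items():
        truth.iloc[k] = [eff.effect_type, eff.beta0, eff.decay_span, eff.growth_rate]

    table = FeatureTable(features=features, intensities=intensities, roles=samples["role"])
    return table, samples, truth


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture(
    table: FeatureTable,
    samples: pd.DataFrame,
    truth: pd.DataFrame | None,
    directory: str | Path,
) -> dict[str, Path]:
    """Write features.tsv / samples.tsv / truth.tsv into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": directory / "features.tsv",
        "samples": directory / "samples.tsv",
    }
    write_feature_table(table, paths["features"])
    write_samples(samples, paths["samples"])
    if truth is not None:
        paths["truth"] = directory / "truth.tsv"
        out = truth.copy()
        out.index.name = "feature_id"
        out.to_csv(paths["truth"], sep="\t")
    return paths


def read_fixture(directory: str | Path) -> tuple[FeatureTable, pd.DataFrame, pd.DataFrame | None]:
    directory = Path(directory)
    samples = read_samples(directory / "samples.tsv")
    table = read_feature_table(directory / "features.tsv", roles=samples["role"])
    truth = None
    tpath = directory / "truth.tsv"
    if tpath.exists():
        # keep_default_na: "null" is an effect type, not missing data
        truth = pd.read_csv(
            tpath, sep="\t", index_col="feature_id", keep_default_na=False, na_values=[""]
        )
    return table, samples, truth


def demo_effects(
    p_features: int,
    n_causal: int = 3,
    n_reactive: int = 3,
    beta0: float = 0.8,
    decay_span: float = 12.0,
) -> list[PlantedEffect]:
    """Planted effects for the shipped demo cohort: effects are spread
    over the feature index range, alternating sign."""
    effects = []
    total = n_causal + n_reactive
    if total > p_features:
        raise ValueError("more effects than features")
    step = max(1, p_features // (total + 1))
    pos = 0
    for i in range(n_causal):
        pos += step
        effects.append(
            PlantedEffect(pos % p_features, "causal", beta0=beta0 if i % 2 == 0 else -beta0)
        )
    for i in range(n_reactive):
        pos += step
        effects.append(
            PlantedEffect(
                pos % p_features,
                "reactive",
                beta0=beta0 if i % 2 == 0 else -beta0,
                decay_span=decay_span,
            )
        )
    return effects
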