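"""Core data containers and their TSV dialects.

A :class:`FeatureTable` pairs a per-feature annotation frame (m/z,
retention time) with an intensity matrix (features x samples) and a
per-sample role tag (``study`` / ``qc`` / ``blank``).  Sample metadata
for study subjects lives in a plain :class:`pandas.DataFrame` (the
"sample frame") indexed by sample id.

All on-disk formats are plain TSV so fixtures round-trip exactly:
Python's float repr is used for serialization, which is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

ROLE_STUDY = "study"
ROLE_QC = "qc"
ROLE_BLANK = "blank"
ROLES = (ROLE_STUDY, ROLE_QC, ROLE_BLANK)

#: columns every sample frame must carry
SAMPLE_COLUMNS = [
    "role",
    "pair_id",
    "caco",
    "gel",
    "batch",
    "age",
    "gender",
    "ttd_years",
]


@dataclass
class FeatureTable:
    """Feature annotations + intensity matrix + per-sample roles.

    Parameters
    ----------
    features:
        Indexed by feature id; must contain ``mz`` and ``rt_sec``.
    intensities:
        Indexed by feature id, one column per sample id; non-negative.
    roles:
        Indexed by sample id with values in :data:`ROLES`.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    roles: pd.Series

    def __post_init__(self) -> None:
        if self.features.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.intensities.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("feature annotation / intensity index mismatch")
        for col in ("mz", "rt_sec"):
            if col not in self.features.columns:
                raise ValueError(f"missing feature column {col!r}")
        missing = set(self.intensities.columns) - set(self.roles.index)
        if missing:
            raise ValueError(f"samples without role tag: {sorted(missing)[:5]}")
        bad_roles = set(self.roles.unique()) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown sample roles: {sorted(bad_roles)}")
        vals = self.intensities.to_numpy()
        if vals.size and (not np.isfinite(vals).all() or (vals < 0).any()):
            raise ValueError("intensities must be finite and non-negative")
        self.roles = self.roles.reindex(self.intensities.columns)

    # -- convenience accessors -------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def n_features(self) -> int:
        return len(self.features)

    def samples_with_role(self, role: str) -> list[str]:
        return list(self.roles.index[self.roles == role])

    def matrix(self, role: str | None = None) -> pd.DataFrame:
        """Intensity sub-matrix restricted to one role (or all samples)."""
        if role is None:
            return self.intensities
        return self.intensities[self.samples_with_role(role)]

    def subset(self, feature_ids) -> "FeatureTable":
        """Restrict to the given feature ids (order preserved)."""
        idx = pd.Index(feature_ids)
        missing = idx.difference(self.features.index)
        if len(missing):
            raise KeyError(f"unknown feature ids: {list(missing)[:5]}")
        return FeatureTable(
            features=self.features.loc[idx].copy(),
            intensities=self.intensities.loc[idx].copy(),
            roles=self.roles.copy(),
        )


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the sample frame contract; returns the frame unchanged."""
    if samples.index.has_duplicates:
        raise ValueError("duplicate sample ids in sample frame")
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample frame missing columns: {missing}")
    study = samples[samples["role"] == ROLE_STUDY]
    bad = set(study["caco"].unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"bad caco labels: {sorted(bad)}")
    counts = study.groupby("pair_id")["caco"].value_counts().unstack(fill_value=0)
    if len(counts) and not ((counts.get("case", 0) == 1) & (counts.get("control", 0) == 1)).all():
        raise ValueError("every pair needs exactly one case and one control")
    return samples


def study_samples(samples: pd.DataFrame) -> pd.DataFrame:
    return samples[samples["role"] == ROLE_STUDY]


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """``features.tsv``: feature_id, mz, rt_sec, then one column per sample."""
    out = pd.concat([table.features[["mz", "rt_sec"]], table.intensities], axis=1)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_feature_table(path: str | Path, roles: pd.Series) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    features = df[["mz", "rt_sec"]]
    intensities = df.drop(columns=["mz", "rt_sec"])
    return FeatureTable(features=features, intensities=intensities, roles=roles)


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_samples(path: str | Path) -> pd.DataFrame:
    # literal "NA" is a meaningful level (QC/blank rows), not missing data
    df = pd.read_csv(
        path, sep="\t", index_col="sample_id", keep_default_na=False, na_values=[""]
    )
    return df


def read_tables(features_path: str | Path, samples_path: str | Path) -> tuple[FeatureTable, pd.DataFrame]:
    """Load the (features.tsv, samples.tsv) pair used across the pipeline."""
    samples = read_samples(samples_path)
    table = read_feature_table(features_path, roles=samples["role"])
    return table, samples
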