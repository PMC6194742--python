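import numpy as np
import pandas as pd
import pytest

from lipidens.synthetic import CohortDesign, NoiseModel, PlantedEffect, generate_cohort
from lipidens.tables import FeatureTable


@pytest.fixture
def tiny_cohort():
    """Small noisy cohort with one causal and one reactive planted effect."""
    design = CohortDesign(n_pairs=8, p_features=30, seed=11, n_qc=4, n_blank=2)
    effects = [
        PlantedEffect(0, "causal", beta0=0.8),
        PlantedEffect(1, "reactive", beta0=0.8, decay_span=20.0),
    ]
    noise = NoiseModel(residual_sd=0.3)
    return generate_cohort(design, effects, noise)


@pytest.fixture
def noise_free_cohort():
    design = CohortDesign(n_pairs=6, p_features=10, seed=5, n_qc=3, n_blank=2)
    effects = [PlantedEffect(0, "causal", beta0=0.6)]
    noise = NoiseModel(residual_sd=0.0, batch_shift_sd=0.0, gel_shift_sd=0.0)
    return generate_cohort(design, effects, noise)


def manual_table(intensity_rows, roles, mz=None, rt=None):
    """Build a FeatureTable from a dict {feature_id: {sample_id: value}}."""
    intens = pd.DataFrame(intensity_rows).T
    n = len(intens)
    features = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(200.0, 800.0, n),
            "rt_sec": rt if rt is not None else np.linspace(60.0, 900.0, n),
        },
        index=intens.index,
    )
    return FeatureTable(
        features=features, intensities=intens, roles=pd.Series(roles, dtype=object)
    )


def paired_samples(n_pairs, ttd=None, batch=None, gel=None, seed=0):
    """Minimal study-only sample frame with n_pairs case/control pairs."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pairs):
        pid = f"P{i+1:02d}"
        t = float(ttd[i]) if ttd is not None else float(rng.uniform(0.5, 14.0))
        b = int(batch[i]) if batch is not None else 1
        for caco in ("case", "control"):
            rows.append(
                {
                    "sample_id": f"{pid}_{caco}",
                    "role": "study",
                    "pair_id": pid,
                    "caco": caco,
                    "gel": int(gel[i]) if gel is not None else 0,
                    "batch": b,
                    "age": 50 + i,
                    "gender": "M" if i % 2 == 0 else "F",
                    "ttd_years": t,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")
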