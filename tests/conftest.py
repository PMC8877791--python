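"""Shared fixtures: small synthetic studies and hand-built tables."""

import numpy as np
import pandas as pd
import pytest

from mlmetab import FeatureTable, PairedSampleSet, SynthConfig, generate


def make_table(values, sample_ids=None, feature_ids=None, tier="untargeted", batch=None):
    """Hand-built FeatureTable from a 2d array."""
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[0])]
    feature_ids = feature_ids or [f"f{j}" for j in range(values.shape[1])]
    intensities = pd.DataFrame(values, index=sample_ids, columns=feature_ids)
    tier_s = pd.Series(tier, index=intensities.columns) if isinstance(tier, str) else tier
    if batch is None:
        batch = pd.Series("B1", index=intensities.index)
    return FeatureTable(intensities, tier_s, batch)


def make_pairs(n, ph_a=7.25, ph_v=7.33, **extra):
    """Minimal PairedSampleSet with n subjects and constant pH."""
    idx = [f"subj{i}" for i in range(n)]
    df = pd.DataFrame(
        {
            "arterial_sample": [f"{s}A" for s in idx],
            "venous_sample": [f"{s}V" for s in idx],
            "ph_arterial": ph_a,
            "ph_venous": ph_v,
        },
        index=idx,
    )
    for k, v in extra.items():
        df[k] = v
    return PairedSampleSet(df)


@pytest.fixture(scope="session")
def small_study():
    """A 12-subject, 20-feature study with planted vessel effects, no nuisance."""
    cfg = SynthConfig(
        n_subjects=12,
        n_features=20,
        vessel_log2fc=(1.0, -0.8, 0.6),
        trait_log2fc=(),
        sigma_within=0.2,
        n_batches=1,
        missing_rate=0.0,
        frac_delayed=0.0,
        delayed_noise_sd=0.0,
        seed=11,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def noisy_study():
    """A study exercising batches, missingness and pH violators."""
    cfg = SynthConfig(
        n_subjects=16,
        n_features=24,
        vessel_log2fc=(1.2,),
        trait_log2fc=(0.9,),
        sigma_within=0.3,
        n_batches=2,
        batch_sd=0.5,
        missing_rate=0.02,
        n_ph_violators=2,
        frac_delayed=0.25,
        delayed_noise_sd=0.4,
        seed=5,
    )
    return generate(cfg)
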