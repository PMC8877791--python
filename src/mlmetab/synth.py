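"""Synthetic paired arterial/venous metabolome generator.

The generator emulates the structure of a paired cord-plasma GC-MS study so
that every downstream stage (pair validation, imputation, batch alignment,
multilevel modeling, permutation inference, univariate follow-up) can be
tested against known ground truth.

Generative model (all on the log2 scale, then exponentiated):

* per-feature baseline ``mu_j ~ Uniform(10, 20)`` (intensities ~1e3-1e6 a.u.);
* subject baseline ``b_ij = mu_j + u_ij`` with ``u_ij ~ N(0, sigma_between^2)``
  — the between-subject component that dominates real cord metabolomes;
* venous log2 intensity ``V_ij = b_ij + eps_ij^V``; arterial
  ``A_ij = b_ij + beta_j + eps_ij^A`` with ``eps ~ N(0, sigma_within^2)`` and
  ``beta_j`` nonzero only on planted vessel-effect features;
* nulliparous subjects get an extra shift ``gamma_j`` on planted
  parity-effect features, applied to the venous sample only (the vessel that
  carries maternal blood);
* additive per-(feature, batch) offsets ``~ N(0, batch_sd^2)``;
* "delayed" subjects (long bench time before freezing) optionally receive
  extra within-subject noise, emulating pre-analytical degradation;
* cells are blanked completely at random at ``missing_rate``.

Defaults mirror a 48-subject study with 416 features (30 MRM, 117 targeted,
269 untargeted), 23/48 nulliparous mothers, and planted fold changes of the
magnitude reported for arteriovenous and parity contrasts in cord plasma.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import FeatureTable, PairedSampleSet

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate",
    "generate_null",
    "VESSEL_FOLD_CHANGES",
    "PARITY_FOLD_CHANGES",
]

#: Arterial/venous fold changes used as default planted vessel effects
#: (magnitudes typical of reported cord-plasma arteriovenous differences;
#: values > 1 higher in the arterial sample).
VESSEL_FOLD_CHANGES = (1.72, 1.48, 1.46, 1.37, 1.36, 1.28, 1.20, 1.17, 0.71, 0.81, 0.88)

#: Parity fold changes used as default planted trait effects on venous
#: intensities (values > 1 higher in infants of nulliparous mothers).
PARITY_FOLD_CHANGES = (
    2.14, 1.98, 1.95, 1.88, 1.78, 1.77, 1.70,
    1.65, 1.59, 1.48, 1.28, 1.26, 1.20, 0.84,
)


class ConfigError(ValueError):
    """Invalid synthetic-data configuration; the message names the field."""


def _log2(fcs: Sequence[float]) -> tuple:
    return tuple(float(np.log2(f)) for f in fcs)


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic paired-metabolome generator.

    Attributes
    ----------
    n_subjects, n_features
        Study size. Defaults: 48 subjects, 416 features.
    vessel_log2fc, trait_log2fc
        Signed log2 fold changes planted on the first
        ``len(vessel_log2fc)`` / next ``len(trait_log2fc)`` features
        (disjoint sets unless ``overlap_effects``).
    trait_prevalence
        Fraction of nulliparous subjects (default 23/48).
    sigma_between, sigma_within
        SD of the subject baseline and of the within-subject vessel noise,
        log2 scale. ``sigma_between`` deliberately dominates.
    n_batches, batch_sd
        Number of acquisition batches (subjects assigned in contiguous
        blocks, both samples of a subject in the same batch) and SD of the
        additive per-(feature, batch) log2 offset.
    missing_rate
        Probability that a cell is blanked, completely at random.
    n_ph_violators
        Number of subject pairs whose pH ordering violates the
        arterial < venous rule (first violator is an exact tie, the rest are
        swapped), for testing the pH-based pair filter.
    frac_delayed, delayed_noise_sd, n_missing_freeze_time
        Fraction of subjects with bench time > 24 h before freezing, the
        extra within-subject noise SD applied to their samples, and how many
        subjects lack a freezing timestamp.
    """

    n_subjects: int = 48
    n_features: int = 416
    vessel_log2fc: tuple = field(default_factory=lambda: _log2(VESSEL_FOLD_CHANGES))
    trait_log2fc: tuple = field(default_factory=lambda: _log2(PARITY_FOLD_CHANGES))
    trait_prevalence: float = 23 / 48
    sigma_between: float = 1.0
    sigma_within: float = 0.52
    n_batches: int = 4
    batch_sd: float = 0.3
    missing_rate: float = 0.00026
    n_ph_violators: int = 0
    frac_delayed: float = 8 / 48
    delayed_noise_sd: float = 0.3
    n_missing_freeze_time: int = 0
    overlap_effects: bool = False
    seed: int = 0

    @property
    def n_vessel_effect_features(self) -> int:
        return len(self.vessel_log2fc)

    @property
    def n_trait_effect_features(self) -> int:
        return len(self.trait_log2fc)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.n_features < 1:
            raise ConfigError("n_features must be >= 1")
        needed = self.n_vessel_effect_features + (
            0 if self.overlap_effects else self.n_trait_effect_features
        )
        if needed > self.n_features:
            raise ConfigError(
                "n_features too small for the requested vessel_log2fc/"
                "trait_log2fc effect features"
            )
        for name in ("sigma_between", "sigma_within", "batch_sd", "delayed_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if not 0 <= self.trait_prevalence <= 1:
            raise ConfigError("trait_prevalence must be in [0, 1]")
        if not 0 <= self.frac_delayed <= 1:
            raise ConfigError("frac_delayed must be in [0, 1]")
        if self.n_batches < 1:
            raise ConfigError("n_batches must be >= 1")
        if not 0 <= self.n_ph_violators <= self.n_subjects:
            raise ConfigError("n_ph_violators must be in [0, n_subjects]")
        if not 0 <= self.n_missing_freeze_time <= self.n_subjects:
            raise ConfigError("n_missing_freeze_time must be in [0, n_subjects]")


@dataclass
class GroundTruth:
    """What was actually planted, for comparison with recovered results."""

    vessel_effects: dict  # feature_id -> true log2 FC (arterial / venous)
    trait_effects: dict  # feature_id -> true log2 FC (nulliparous / multiparous)
    effects_disjoint: bool
    batch_of_sample: pd.Series
    missing_mask: pd.DataFrame  # samples x features, True where blanked
    ph_violators: list  # subject ids violating arterial < venous
    delayed_subjects: list  # subject ids with bench time > 24 h

    def as_dict(self) -> dict:
        return {
            "vessel_effects": {k: float(v) for k, v in self.vessel_effects.items()},
            "trait_effects": {k: float(v) for k, v in self.trait_effects.items()},
            "effects_disjoint": self.effects_disjoint,
            "ph_violators": list(self.ph_violators),
            "delayed_subjects": list(self.delayed_subjects),
            "n_missing_cells": int(self.missing_mask.to_numpy().sum()),
        }


def _tier_assignment(n_features: int) -> np.ndarray:
    """Split features over tiers in the 30:117:269 proportion."""
    props = np.array([30, 117, 269], dtype=float)
    props /= props.sum()
    n_mrm = max(1, int(round(props[0] * n_features))) if n_features >= 3 else 0
    n_tar = max(1, int(round(props[1] * n_features))) if n_features >= 3 else 0
    if n_features < 3:
        return np.array(["untargeted"] * n_features)
    n_unt = n_features - n_mrm - n_tar
    return np.array(["mrm"] * n_mrm + ["targeted"] * n_tar + ["untargeted"] * n_unt)


def generate(config: SynthConfig) -> tuple[FeatureTable, PairedSampleSet, GroundTruth]:
    """Generate one synthetic paired arterial/venous metabolome study.

    Returns the feature table (linear intensities with missing cells), the
    paired sample set with traits and cord pH, and the planted ground truth.
    Fully deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n, p = config.n_subjects, config.n_features

    subject_ids = [f"subj{i + 1:03d}" for i in range(n)]
    feature_ids = [f"F{j + 1:04d}" for j in range(p)]
    arterial_ids = [f"{s}A" for s in subject_ids]
    venous_ids = [f"{s}V" for s in subject_ids]

    # planted effect vectors
    beta = np.zeros(p)
    gamma = np.zeros(p)
    nv = config.n_vessel_effect_features
    beta[:nv] = config.vessel_log2fc
    t0 = 0 if config.overlap_effects else nv
    gamma[t0 : t0 + config.n_trait_effect_features] = config.trait_log2fc

    # subject traits
    n_nulli = int(round(config.trait_prevalence * n))
    parity = np.array(["multiparous"] * n)
    parity[rng.permutation(n)[:n_nulli]] = "nulliparous"
    sex = rng.choice(["female", "male"], size=n)
    gest = np.clip(rng.normal(280, 8, size=n), 210, 300).round()
    bw = np.clip(rng.normal(3510, 420, size=n), 1500, 5500).round()
    age = np.clip(rng.normal(29, 4.5, size=n), 18, 45).round(1)
    bmi = np.clip(rng.normal(24.5, 3.5, size=n), 16, 45).round(1)

    # bench time before freezing; "delayed" subjects exceed 24 h
    n_delayed = int(round(config.frac_delayed * n))
    delayed_idx = np.sort(rng.permutation(n)[:n_delayed])
    hours = rng.uniform(2, 23, size=n)
    hours[delayed_idx] = rng.uniform(25, 48, size=n_delayed)
    hours = hours.round(1)

    # log2 intensity construction
    mu = rng.uniform(10, 20, size=p)
    u = rng.normal(0.0, config.sigma_between, size=(n, p))
    eps_a = rng.normal(0.0, config.sigma_within, size=(n, p))
    eps_v = rng.normal(0.0, config.sigma_within, size=(n, p))
    if config.delayed_noise_sd > 0 and n_delayed:
        eps_a[delayed_idx] += rng.normal(
            0.0, config.delayed_noise_sd, size=(n_delayed, p)
        )
        eps_v[delayed_idx] += rng.normal(
            0.0, config.delayed_noise_sd, size=(n_delayed, p)
        )
    is_nulli = (parity == "nulliparous").astype(float)[:, None]

    log_a = mu + u + beta[None, :] + eps_a
    log_v = mu + u + is_nulli * gamma[None, :] + eps_v

    # batches: contiguous subject blocks, both vessels of a subject together
    batch_of_subject = np.minimum(
        (np.arange(n) * config.n_batches) // max(n, 1), config.n_batches - 1
    )
    batch_labels = np.array([f"B{b + 1}" for b in batch_of_subject])
    offsets = rng.normal(0.0, config.batch_sd, size=(config.n_batches, p))
    log_a = log_a + offsets[batch_of_subject]
    log_v = log_v + offsets[batch_of_subject]

    # assemble sample x feature matrix, arterial rows then venous rows
    log_all = np.vstack([log_a, log_v])
    sample_ids = arterial_ids + venous_ids
    intensities = pd.DataFrame(
        np.exp2(log_all), index=pd.Index(sample_ids, name="sample_id"),
        columns=feature_ids,
    )

    # missingness, completely at random
    mask = rng.random(size=intensities.shape) < config.missing_rate
    intensities = intensities.mask(mask)
    missing_mask = pd.DataFrame(
        mask, index=intensities.index, columns=intensities.columns
    )

    # cord pH: arterial below venous except for injected violators
    ph_v = rng.normal(7.32, 0.05, size=n)
    diff = np.abs(rng.normal(0.07, 0.02, size=n))
    ph_a = ph_v - diff
    violator_idx = np.sort(rng.permutation(n)[: config.n_ph_violators])
    for k, i in enumerate(violator_idx):
        if k == 0:
            ph_a[i] = ph_v[i]  # exact tie, also a rule violation
        else:
            ph_a[i], ph_v[i] = ph_v[i], ph_a[i]
    ph_a, ph_v = ph_a.round(3), ph_v.round(3)

    hours_col = hours.astype(object)
    if config.n_missing_freeze_time:
        miss_idx = rng.permutation(n)[: config.n_missing_freeze_time]
        for i in miss_idx:
            hours_col[i] = np.nan

    subjects = pd.DataFrame(
        {
            "arterial_sample": arterial_ids,
            "venous_sample": venous_ids,
            "ph_arterial": ph_a,
            "ph_venous": ph_v,
            "parity": parity,
            "sex": sex,
            "gestational_length": gest,
            "birth_weight": bw,
            "maternal_age": age,
            "maternal_bmi": bmi,
            "hours_to_freezing": pd.to_numeric(hours_col),
            "batch": batch_labels,
        },
        index=pd.Index(subject_ids, name="subject_id"),
    )

    batch_series = pd.Series(
        np.concatenate([batch_labels, batch_labels]),
        index=intensities.index,
    )
    table = FeatureTable(
        intensities,
        pd.Series(_tier_assignment(p), index=intensities.columns),
        batch_series,
    )
    pairs = PairedSampleSet(subjects)
    truth = GroundTruth(
        vessel_effects={feature_ids[j]: beta[j] for j in range(nv)},
        trait_effects={
            feature_ids[t0 + k]: config.trait_log2fc[k]
            for k in range(config.n_trait_effect_features)
        },
        effects_disjoint=not config.overlap_effects,
        batch_of_sample=batch_series.copy(),
        missing_mask=missing_mask,
        ph_violators=[subject_ids[i] for i in violator_idx],
        delayed_subjects=[subject_ids[i] for i in delayed_idx],
    )
    return table, pairs, truth


def generate_null(
    config: SynthConfig,
) -> tuple[FeatureTable, PairedSampleSet, GroundTruth]:
    """Same generative model with every planted effect forced to zero."""
    config.validate()
    null_cfg = replace(config, vessel_log2fc=(), trait_log2fc=())
    return generate(null_cfg)
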