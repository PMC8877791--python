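"""End-to-end orchestration of the paired cord-plasma workflow.

Stage order for the vessel analysis mirrors the study workflow: pH-based
pair validation -> imputation -> batch alignment -> effect matrix ->
multilevel design -> repeated double CV random forest -> performance gate
-> (if the gate passes) permutation test -> univariate follow-up table.
Trait analyses model one vessel's samples at a time against a trait, with
classification for dichotomous traits and Q2 regression for continuous
ones. A sensitivity analysis re-runs everything on the subset of subjects
whose samples reached the freezer quickly, and a freezing-time check
regresses bench time on the metabolome to rule out systematic handling
effects.

Every report is a plain dict (JSON-serializable) that records the
parameters, seeds, stage log, and fold-assignment digest needed to audit a
run; reports are byte-identical across runs with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import FeatureTable, PairedSampleSet
from .inference import performance_gate, permutation_test
from .multilevel import build_design, build_effect_matrix
from .preprocess import align_batches, clean_nonpositive, impute, validate_pairs
from .rdcv import RandomForestRdCV
from .synth import SynthConfig, generate
from .univariate import replication_test, trait_table, vessel_table

__all__ = [
    "RunConfig",
    "run_vessel_analysis",
    "run_trait_analysis",
    "run_sensitivity",
    "run_freezing_time_check",
    "run_all",
]

#: Trait -> (type, positive level, negative level); continuous traits map to None.
DICHOTOMOUS = {
    "parity": ("nulliparous", "multiparous"),
    "sex": ("female", "male"),
}
CONTINUOUS_TRAITS = (
    "gestational_length",
    "birth_weight",
    "maternal_age",
    "maternal_bmi",
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    rdcv: dict = field(
        default_factory=lambda: {
            "n_rep": 5,
            "n_outer": 6,
            "n_inner": 5,
            "var_ratio": 0.75,
            "min_features": 2,
            "n_trees": 151,
        }
    )
    perm_rdcv: dict = field(
        default_factory=lambda: {
            "n_rep": 1,
            "n_outer": 3,
            "n_inner": 2,
            "var_ratio": 0.5,
            "min_features": 5,
            "n_trees": 15,
            "fitness": "q2",
            "fit_final_model": False,
        }
    )
    n_perm: int = 1000
    q2_threshold: float = 0.2
    cr_threshold: float = 0.66
    traits: tuple = ("parity", "sex", "gestational_length", "birth_weight",
                     "maternal_age", "maternal_bmi")
    sensitivity_max_hours: float = 24.0
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if self.q2_threshold <= 0 or self.cr_threshold <= 0:
            raise ValueError("gate thresholds must be positive")
        if self.sensitivity_max_hours <= 0:
            raise ValueError("sensitivity_max_hours must be positive")

    # -- yaml round trip -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["synth"] = dataclasses.asdict(self.synth)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        synth = d.pop("synth", {})
        for key in ("vessel_log2fc", "trait_log2fc"):
            if key in synth and synth[key] is not None:
                synth[key] = tuple(synth[key])
        d["traits"] = tuple(d.get("traits", cls.traits))
        return cls(synth=SynthConfig(**synth), **d)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _seed_for(config: RunConfig, label: str) -> int:
    digest = hashlib.sha256(f"{config.seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31

def _digest_folds(fold_assignments: np.ndarray) -> str:
    return hashlib.sha256(fold_assignments.tobytes()).hexdigest()[:16]


def preprocess_tables(
    table: FeatureTable, pairs: PairedSampleSet
) -> tuple[FeatureTable, PairedSampleSet, dict]:
    """Pair validation, imputation and batch alignment, with a stage log."""
    val = validate_pairs(pairs)
    kept = val.kept
    sample_ids = list(kept.subjects["arterial_sample"]) + list(
        kept.subjects["venous_sample"]
    )
    sub = table.subset_samples([s for s in table.sample_ids if s in set(sample_ids)])
    sub = clean_nonpositive(sub)
    missing_before = sub.missing_fraction()
    sub = impute(sub)
    sub = align_batches(sub)
    log = {
        "n_pairs_in": int(pairs.n_subjects),
        "n_pairs_kept": int(kept.n_subjects),
        "removed_ph_rule": list(map(str, val.removed)),
        "excluded_missing_ph": list(map(str, val.excluded_missing_ph)),
        "missing_fraction_before_imputation": float(missing_before),
    }
    return sub, kept, log


def _fit_fn_factory(params: dict, fitness: str):
    """A permutation-refit function over reduced rdCV settings."""

    def fit_fn(X, y, groups, seed):
        model = RandomForestRdCV(**{**params, "random_state": seed})
        model.fit(X, y, groups=groups)
        return model.result_.fitness["mid"]

    return fit_fn


def _prediction_plot_data(result) -> dict:
    """Per-repetition (grey) and averaged (black) out-of-fold predictions."""
    return {
        "per_repetition": np.asarray(
            result.oof_per_rep["mid"]
        ).round(6).tolist(),
        "averaged": np.asarray(result.oof_mean["mid"]).round(6).tolist(),
        "targets": np.asarray(result.y_units).tolist(),
    }


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------

def run_vessel_analysis(
    table: FeatureTable,
    pairs: PairedSampleSet,
    config: RunConfig,
    annotations: pd.Series | None = None,
) -> dict:
    """Multilevel arterial-versus-venous analysis, preprocessing included."""
    config.validate()
    stages = []
    try:
        stages.append("validate_pairs")
        clean, kept, pre_log = preprocess_tables(table, pairs)
        stages.extend(["impute", "align_batches"])

        stages.append("effect_matrix")
        E = build_effect_matrix(clean, kept)
        design = build_design(E)

        stages.append("rdcv_fit")
        model = RandomForestRdCV(
            fitness="classification_rate",
            random_state=_seed_for(config, "vessel"),
            **config.rdcv,
        )
        model.fit(design.X, design.y, groups=design.groups)
        res = model.result_
        cr = res.fitness["mid"]

        stages.append("gate")
        gate_pass = performance_gate(
            "classification_rate", cr,
            q2_threshold=config.q2_threshold, cr_threshold=config.cr_threshold,
        )
        perm = None
        if gate_pass and config.n_perm > 0:
            stages.append("permutation_test")
            fit_fn = _fit_fn_factory(config.perm_rdcv, "q2")
            perm = permutation_test(
                fit_fn,
                design.X.to_numpy(),
                design.y,
                groups=design.groups,
                n_perm=config.n_perm,
                seed=_seed_for(config, "vessel-perm"),
                scheme="signflip",
            )

        stages.append("univariate")
        uni = vessel_table(
            E,
            clean.log2(),
            list(kept.subjects["arterial_sample"]),
            list(kept.subjects["venous_sample"]),
            res.selected["mid"],
            annotations=annotations,
        )

        report = {
            "analysis": "vessel",
            "software_version": __version__,
            "seed": config.seed,
            "preprocessing": pre_log,
            "n_subjects": int(kept.n_subjects),
            "n_features": int(clean.n_features),
            "rdcv_params": model.get_params(),
            "fold_digest": _digest_folds(res.fold_assignments),
            "classification_rate": float(cr),
            "fitness_all_sizes": {k: float(v) for k, v in res.fitness.items()},
            "n_features_selected": res.n_features,
            "selected_mid": list(res.selected["mid"]),
            "gate_passed": bool(gate_pass),
            "permutation": None if perm is None else perm.as_dict(),
            "univariate_table": uni.to_dict(orient="records"),
            "prediction_plot": _prediction_plot_data(res),
            "stages": stages,
        }
        return report
    except Exception as exc:  # noqa: BLE001 - stage-named rethrow
        if isinstance(exc, StageError):
            raise
        raise StageError(f"vessel analysis failed at stage {stages[-1]!r}: {exc}") from exc


def _trait_xy(
    clean: FeatureTable, kept: PairedSampleSet, vessel: str, trait: str
):
    """Per-sample standardized log2 intensities and the trait target."""
    sample_ids = kept.subjects[f"{vessel}_sample"]
    X = clean.log2().loc[sample_ids]
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    X = (X - mu) / sd.replace(0, 1.0)
    vals = kept.subjects[trait]
    if trait in DICHOTOMOUS:
        pos, neg = DICHOTOMOUS[trait]
        y = vals.map({pos: 1.0, neg: -1.0}).to_numpy()
        kind = "classification_rate"
    else:
        y = pd.to_numeric(vals, errors="coerce").to_numpy(dtype=float)
        kind = "q2"
    keep = np.isfinite(y)
    return X.loc[keep], y[keep], kind


def run_trait_analysis(
    table: FeatureTable,
    pairs: PairedSampleSet,
    trait: str,
    config: RunConfig,
    annotations: pd.Series | None = None,
    _preprocessed: tuple | None = None,
) -> dict:
    """Model one trait against the arterial and venous metabolomes separately."""
    config.validate()
    if trait not in pairs.subjects.columns:
        raise StageError(f"trait analysis failed at stage 'input': no column {trait!r}")
    if pairs.subjects[trait].nunique(dropna=True) < 2:
        raise StageError(
            f"trait analysis failed at stage 'input': trait {trait!r} is constant"
        )
    if _preprocessed is None:
        clean, kept, pre_log = preprocess_tables(table, pairs)
    else:
        clean, kept, pre_log = _preprocessed

    report = {
        "analysis": "trait",
        "trait": trait,
        "software_version": __version__,
        "seed": config.seed,
        "preprocessing": pre_log,
        "vessels": {},
    }
    for vessel in ("arterial", "venous"):
        X, y, kind = _trait_xy(clean, kept, vessel, trait)
        if kind == "classification_rate":
            levels, counts = np.unique(y, return_counts=True)
            if len(levels) < 2 or counts.min() < 2:
                raise StageError(
                    f"trait analysis failed at stage 'input': trait {trait!r} "
                    "needs >= 2 subjects per class"
                )
        stages = ["rdcv_fit"]
        model = RandomForestRdCV(
            fitness=kind,
            random_state=_seed_for(config, f"trait-{trait}-{vessel}"),
            **config.rdcv,
        )
        model.fit(X, y)
        res = model.result_
        fitness = res.fitness["mid"]

        stages.append("gate")
        gate_pass = performance_gate(
            kind, fitness,
            q2_threshold=config.q2_threshold, cr_threshold=config.cr_threshold,
        )
        perm = None
        if gate_pass and config.n_perm > 0:
            stages.append("permutation_test")
            fit_fn = _fit_fn_factory(config.perm_rdcv, "q2")
            perm = permutation_test(
                fit_fn,
                X.to_numpy(),
                y,
                groups=None,
                n_perm=config.n_perm,
                seed=_seed_for(config, f"trait-{trait}-{vessel}-perm"),
                scheme="labels",
            )

        uni = None
        if (
            kind == "classification_rate"
            and perm is not None
            and perm.p_value < 0.05
        ):
            stages.append("univariate")
            pos, neg = DICHOTOMOUS[trait]
            labels = kept.subjects.set_index(f"{vessel}_sample")[trait]
            raw = clean.intensities.loc[labels.index]
            uni = trait_table(
                raw, labels, pos, neg, res.selected["mid"], annotations=annotations
            ).to_dict(orient="records")

        report["vessels"][vessel] = {
            "fitness_kind": kind,
            "fitness": float(fitness),
            "n": int(len(y)),
            "rdcv_params": model.get_params(),
            "fold_digest": _digest_folds(res.fold_assignments),
            "n_features_selected": res.n_features,
            "selected_mid": list(res.selected["mid"]),
            "gate_passed": bool(gate_pass),
            "permutation": None if perm is None else perm.as_dict(),
            "univariate_table": uni,
            "prediction_plot": _prediction_plot_data(res),
            "stages": stages,
        }
    return report


def run_sensitivity(
    table: FeatureTable,
    pairs: PairedSampleSet,
    config: RunConfig,
    traits: tuple = ("parity",),
    full_vessel: dict | None = None,
    full_traits: dict | None = None,
) -> dict:
    """Re-run vessel and trait analyses on quickly-frozen samples only.

    Subjects whose bench time exceeds ``config.sensitivity_max_hours`` are
    dropped; the report juxtaposes full-cohort and subset fitness.
    Already-computed full-cohort reports can be passed in to avoid
    refitting them; subset re-runs skip permutation testing (the
    comparison is about fitness, not inference).
    """
    config.validate()
    if "hours_to_freezing" not in pairs.subjects.columns:
        raise StageError("sensitivity failed at stage 'input': no hours_to_freezing")
    hours = pd.to_numeric(pairs.subjects["hours_to_freezing"], errors="coerce")
    keep_ids = pairs.subjects.index[hours <= config.sensitivity_max_hours]
    if len(keep_ids) < 2 * config.rdcv.get("n_outer", 6):
        raise StageError(
            "sensitivity failed at stage 'subset': "
            f"only {len(keep_ids)} subjects pass the <= "
            f"{config.sensitivity_max_hours} h filter; need at least "
            f"{2 * config.rdcv.get('n_outer', 6)} for the outer folds"
        )
    subset = pairs.subset(keep_ids)

    no_perm = dataclasses.replace(config, n_perm=0)
    if full_vessel is None:
        full_vessel = run_vessel_analysis(table, pairs, no_perm)
    sub_vessel = run_vessel_analysis(table, subset, no_perm)
    out = {
        "analysis": "sensitivity",
        "max_hours": float(config.sensitivity_max_hours),
        "n_full": int(pairs.n_subjects),
        "n_subset": int(subset.n_subjects),
        "vessel": {
            "full_classification_rate": full_vessel["classification_rate"],
            "subset_classification_rate": sub_vessel["classification_rate"],
        },
        "traits": {},
    }
    for trait in traits:
        if full_traits is not None and trait in full_traits:
            full_t = full_traits[trait]
        else:
            full_t = run_trait_analysis(table, pairs, trait, no_perm)
        sub_t = run_trait_analysis(table, subset, trait, no_perm)
        out["traits"][trait] = {
            vessel: {
                "full": full_t["vessels"][vessel]["fitness"],
                "subset": sub_t["vessels"][vessel]["fitness"],
            }
            for vessel in ("arterial", "venous")
        }
    return out


def run_freezing_time_check(
    table: FeatureTable, pairs: PairedSampleSet, config: RunConfig
) -> dict:
    """Regress bench time until freezing on the metabolome (per vessel).

    A Q2 at or below the gate threshold rules out systematic pre-analytical
    effects from delayed freezing. Subjects without a timestamp are dropped
    and the effective n reported.
    """
    config.validate()
    if "hours_to_freezing" not in pairs.subjects.columns:
        raise StageError("freezing check failed at stage 'input': no hours_to_freezing")
    clean, kept, pre_log = preprocess_tables(table, pairs)
    out = {"analysis": "freezing_time", "preprocessing": pre_log, "vessels": {}}
    for vessel in ("arterial", "venous"):
        X, y, _ = _trait_xy(clean, kept, vessel, "hours_to_freezing")
        if np.ptp(y) == 0:
            raise StageError(
                "freezing check failed at stage 'input': constant freezing time"
            )
        model = RandomForestRdCV(
            fitness="q2",
            random_state=_seed_for(config, f"freeze-{vessel}"),
            **config.rdcv,
        )
        model.fit(X, y)
        q2 = model.result_.fitness["mid"]
        out["vessels"][vessel] = {
            "q2": float(q2),
            "n": int(len(y)),
            "gate_passed": bool(
                performance_gate(
                    "q2", q2,
                    q2_threshold=config.q2_threshold,
                    cr_threshold=config.cr_threshold,
                )
            ),
        }
    return out


def run_all(
    table: FeatureTable,
    pairs: PairedSampleSet,
    config: RunConfig,
    prior_parity: pd.DataFrame | None = None,
) -> dict:
    """Full study workflow; optionally writes reports under ``config.out_dir``."""
    config.validate()
    report = {
        "software_version": __version__,
        "seed": config.seed,
        "vessel": run_vessel_analysis(table, pairs, config),
        "traits": {},
    }
    clean, kept, pre_log = preprocess_tables(table, pairs)
    for trait in config.traits:
        report["traits"][trait] = run_trait_analysis(
            table, pairs, trait, config, _preprocessed=(clean, kept, pre_log)
        )
    if "hours_to_freezing" in pairs.subjects.columns:
        report["freezing_time"] = run_freezing_time_check(table, pairs, config)
        sens_traits = tuple(t for t in ("parity",) if t in config.traits)
        report["sensitivity"] = run_sensitivity(
            table, pairs, config, traits=sens_traits,
            full_vessel=report["vessel"],
            full_traits={t: report["traits"][t] for t in sens_traits},
        )
    if prior_parity is not None:
        labels = kept.subjects.set_index("venous_sample")["parity"]
        ven = clean.intensities.loc[labels.index]
        report["replication_parity_venous"] = replication_test(
            ven, labels, prior_parity, "nulliparous", "multiparous"
        ).to_dict(orient="records")
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        uni = report["vessel"]["univariate_table"]
        pd.DataFrame(uni).to_csv(out / "vessel_univariate.csv", index=False)
    return report


def simulate_study(config: RunConfig):
    """Generate the synthetic study described by ``config.synth``."""
    return generate(config.synth)
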