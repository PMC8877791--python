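"""Core data containers for paired-cord-plasma metabolome analysis.

Two containers travel through the whole pipeline:

``FeatureTable``
    A samples x features matrix of strictly positive (or missing) intensities
    in arbitrary units, with a per-feature acquisition tier annotation
    (``mrm`` / ``targeted`` / ``untargeted``) and a per-sample batch label.

``PairedSampleSet``
    One row per subject, linking the subject's arterial and venous sample ids
    and carrying cord pH per vessel plus maternal/infant traits (parity, sex,
    gestational length, birth weight, maternal age, maternal BMI) and sample
    handling time.

Both are thin, validated wrappers around :class:`pandas.DataFrame` and are
round-trippable through plain CSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TIERS = ("mrm", "targeted", "untargeted")

#: Deduplication priority when merging acquisition tiers (best first).
TIER_PRIORITY = {"mrm": 0, "targeted": 1, "untargeted": 2}

VESSELS = ("arterial", "venous")
PARITY_LEVELS = ("nulliparous", "multiparous")
SEX_LEVELS = ("female", "male")

#: Subject-level trait columns expected in a :class:`PairedSampleSet`.
TRAIT_COLUMNS = (
    "parity",
    "sex",
    "gestational_length",
    "birth_weight",
    "maternal_age",
    "maternal_bmi",
)


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass
class FeatureTable:
    """Samples x features intensity matrix with tier and batch annotations.

    Parameters
    ----------
    intensities
        DataFrame indexed by sample id with feature ids as columns. Values
        are strictly positive intensities in arbitrary units; missing values
        are ``NaN``.
    tier
        Series indexed by feature id with values in :data:`TIERS`.
    batch
        Series indexed by sample id with arbitrary hashable batch labels.
    """

    intensities: pd.DataFrame
    tier: pd.Series
    batch: pd.Series

    def __post_init__(self) -> None:
        idx = self.intensities.index
        cols = self.intensities.columns
        if idx.has_duplicates:
            raise ValidationError("duplicate sample ids in feature table")
        if cols.has_duplicates:
            raise ValidationError("duplicate feature ids in feature table")
        self.tier = self.tier.reindex(cols)
        if self.tier.isna().any():
            missing = self.tier.index[self.tier.isna()].tolist()
            raise ValidationError(f"features without tier annotation: {missing[:5]}")
        bad = set(self.tier.unique()) - set(TIERS)
        if bad:
            raise ValidationError(f"unknown tiers {sorted(bad)}; expected {TIERS}")
        self.batch = self.batch.reindex(idx)
        if self.batch.isna().any():
            missing = self.batch.index[self.batch.isna()].tolist()
            raise ValidationError(f"samples without batch label: {missing[:5]}")
        values = self.intensities.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(values <= 0):
                raise ValidationError(
                    "non-positive intensities present; convert to missing first"
                )

    # -- basic introspection -------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def missing_fraction(self) -> float:
        """Fraction of missing cells in the intensity matrix."""
        return float(self.intensities.isna().to_numpy().mean())

    def tier_counts(self) -> dict[str, int]:
        """Number of features per acquisition tier."""
        counts = self.tier.value_counts()
        return {t: int(counts.get(t, 0)) for t in TIERS}

    # -- manipulation --------------------------------------------------------

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.tier.copy(), self.batch.copy()
        )

    def subset_samples(self, sample_ids) -> "FeatureTable":
        """Restrict the table to ``sample_ids`` (order preserved)."""
        sample_ids = pd.Index(sample_ids)
        unknown = sample_ids.difference(self.sample_ids)
        if len(unknown):
            raise ValidationError(f"unknown sample ids: {list(unknown[:5])}")
        return FeatureTable(
            self.intensities.loc[sample_ids],
            self.tier.copy(),
            self.batch.loc[sample_ids],
        )

    def subset_features(self, feature_ids) -> "FeatureTable":
        feature_ids = pd.Index(feature_ids)
        unknown = feature_ids.difference(self.feature_ids)
        if len(unknown):
            raise ValidationError(f"unknown feature ids: {list(unknown[:5])}")
        return FeatureTable(
            self.intensities.loc[:, feature_ids],
            self.tier.loc[feature_ids],
            self.batch.copy(),
        )

    def log2(self) -> pd.DataFrame:
        """Log2-transformed intensities (missing stays missing)."""
        return np.log2(self.intensities)

    # -- i/o -----------------------------------------------------------------

    def to_dir(self, out_dir: str | Path) -> None:
        """Write ``features.csv`` and ``feature_meta.csv`` under ``out_dir``.

        Batch labels are not written here; they live in the sample metadata
        file written by :meth:`PairedSampleSet.to_csv` callers or the CLI.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.intensities.rename_axis("sample_id").to_csv(out / "features.csv")
        meta = pd.DataFrame({"feature_id": self.feature_ids, "tier": self.tier.values})
        meta.to_csv(out / "feature_meta.csv", index=False)

    @classmethod
    def from_csv(
        cls,
        features_csv: str | Path,
        feature_meta_csv: str | Path | None,
        batch: pd.Series,
    ) -> "FeatureTable":
        """Load a table from ``features.csv`` (+ optional tier metadata)."""
        intensities = pd.read_csv(features_csv, index_col=0)
        intensities.index = intensities.index.astype(str)
        if feature_meta_csv is not None:
            meta = pd.read_csv(feature_meta_csv)
            tier = pd.Series(
                meta["tier"].values, index=meta["feature_id"].astype(str)
            )
        else:
            tier = pd.Series("untargeted", index=intensities.columns)
        batch = batch.copy()
        batch.index = batch.index.astype(str)
        return cls(intensities, tier, batch)


@dataclass
class PairedSampleSet:
    """Subject-keyed arterial/venous sample pairs with traits and cord pH.

    ``subjects`` is indexed by subject id and must carry the columns
    ``arterial_sample``, ``venous_sample``, ``ph_arterial``, ``ph_venous``
    plus the traits in :data:`TRAIT_COLUMNS`. ``hours_to_freezing`` (time
    from sampling until the plasma aliquot reached the freezer) is optional
    but required for sensitivity analyses.
    """

    subjects: pd.DataFrame
    required: tuple = field(
        default=("arterial_sample", "venous_sample", "ph_arterial", "ph_venous"),
        repr=False,
    )

    def __post_init__(self) -> None:
        df = self.subjects
        if df.index.has_duplicates:
            raise ValidationError("duplicate subject ids")
        for col in self.required:
            if col not in df.columns:
                raise ValidationError(f"missing required column {col!r}")
        all_samples = pd.concat([df["arterial_sample"], df["venous_sample"]])
        if all_samples.duplicated().any():
            raise ValidationError("a sample id is assigned to more than one slot")
        if "parity" in df.columns:
            bad = set(df["parity"].dropna().unique()) - set(PARITY_LEVELS)
            if bad:
                raise ValidationError(f"invalid parity levels {sorted(bad)}")
        if "sex" in df.columns:
            bad = set(df["sex"].dropna().unique()) - set(SEX_LEVELS)
            if bad:
                raise ValidationError(f"invalid sex levels {sorted(bad)}")
        for col, lo, hi in (
            ("gestational_length", 150, 330),
            ("birth_weight", 300, 7000),
            ("maternal_age", 12, 60),
            ("maternal_bmi", 10, 70),
        ):
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce").dropna()
                if len(vals) and ((vals < lo) | (vals > hi)).any():
                    raise ValidationError(
                        f"{col} outside plausible range [{lo}, {hi}]"
                    )

    @property
    def subject_ids(self) -> pd.Index:
        return self.subjects.index

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def copy(self) -> "PairedSampleSet":
        return PairedSampleSet(self.subjects.copy())

    def subset(self, subject_ids) -> "PairedSampleSet":
        subject_ids = pd.Index(subject_ids)
        unknown = subject_ids.difference(self.subjects.index)
        if len(unknown):
            raise ValidationError(f"unknown subject ids: {list(unknown[:5])}")
        return PairedSampleSet(self.subjects.loc[subject_ids].copy())

    def sample_ids(self, vessel: str) -> pd.Series:
        """Sample ids of one vessel, indexed by subject id."""
        if vessel not in VESSELS:
            raise ValidationError(f"vessel must be one of {VESSELS}, got {vessel!r}")
        return self.subjects[f"{vessel}_sample"]

    # -- i/o -----------------------------------------------------------------

    def to_sample_metadata(self) -> pd.DataFrame:
        """Long-format per-sample metadata table (two rows per subject)."""
        rows = []
        for sid, row in self.subjects.iterrows():
            for vessel in VESSELS:
                rec = {
                    "sample_id": row[f"{vessel}_sample"],
                    "subject_id": sid,
                    "vessel": vessel,
                    "ph": row[f"ph_{vessel}"],
                }
                for col in self.subjects.columns:
                    if col in (
                        "arterial_sample",
                        "venous_sample",
                        "ph_arterial",
                        "ph_venous",
                    ):
                        continue
                    rec[col] = row[col]
                rows.append(rec)
        return pd.DataFrame(rows).set_index("sample_id")

    def to_csv(self, path: str | Path) -> None:
        self.to_sample_metadata().to_csv(path)

    @classmethod
    def from_sample_metadata(cls, meta: pd.DataFrame) -> "PairedSampleSet":
        """Build from a long-format per-sample metadata table.

        ``meta`` must be indexed by sample id and carry ``subject_id``,
        ``vessel`` and ``ph`` columns; any further columns are treated as
        subject-level traits (must be identical across a subject's samples).
        """
        meta = meta.copy()
        records = {}
        trait_cols = [
            c for c in meta.columns if c not in ("subject_id", "vessel", "ph")
        ]
        for sid, grp in meta.groupby("subject_id", sort=True):
            vessels = set(grp["vessel"])
            if vessels != set(VESSELS):
                raise ValidationError(
                    f"subject {sid!r} lacks exactly one sample per vessel"
                )
            art = grp[grp["vessel"] == "arterial"].iloc[0]
            ven = grp[grp["vessel"] == "venous"].iloc[0]
            rec = {
                "arterial_sample": art.name,
                "venous_sample": ven.name,
                "ph_arterial": art["ph"],
                "ph_venous": ven["ph"],
            }
            for col in trait_cols:
                vals = grp[col].unique()
                rec[col] = vals[0]
            records[sid] = rec
        return cls(pd.DataFrame.from_dict(records, orient="index"))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairedSampleSet":
        meta = pd.read_csv(path, index_col=0)
        meta.index = meta.index.astype(str)
        return cls.from_sample_metadata(meta)
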