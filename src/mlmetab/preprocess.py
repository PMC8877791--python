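"""Feature-table preprocessing: tier merging, pair validation, imputation,
and batch intensity alignment.

The stages mirror a typical GC-MS metabolomics workflow for paired cord
plasma samples:

1. :func:`merge_tiers` combines the MRM, targeted and untargeted feature
   tables into one, dropping duplicate measurements of the same metabolite
   with priority MRM > targeted > untargeted.
2. :func:`validate_pairs` removes subject pairs whose arterial pH is not
   strictly below the venous pH (wrong-vessel sampling check).
3. :func:`impute` fills sparse missing values by iterative low-rank matrix
   completion on the log2 scale (PLS-family latent-structure imputation).
4. :func:`align_batches` removes additive per-(feature, batch) intensity
   offsets by median matching on the log2 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import TIER_PRIORITY, FeatureTable, PairedSampleSet, ValidationError

__all__ = [
    "merge_tiers",
    "validate_pairs",
    "PairValidationResult",
    "clean_nonpositive",
    "LowRankImputer",
    "impute",
    "align_batches",
]


class AlignmentError(ValueError):
    """Sample ids of the tier tables do not line up."""


class UnimputableError(ValueError):
    """A sample or feature is entirely missing and cannot be imputed."""


# ---------------------------------------------------------------------------
# tier merging
# ---------------------------------------------------------------------------

def merge_tiers(
    mrm: FeatureTable,
    targeted: FeatureTable,
    untargeted: FeatureTable,
    identity_map: list[tuple[str, str]] | None = None,
) -> FeatureTable:
    """Merge the three acquisition tiers into a single feature table.

    ``identity_map`` lists pairs of feature ids (across any two tables) known
    to measure the same metabolite. Within each equivalence class only the
    copy from the highest-priority tier (MRM > targeted > untargeted) is
    retained; lower-priority duplicates are dropped.

    Raises
    ------
    AlignmentError
        If the three tables do not share an identical sample-id set.
    ValidationError
        If the identity map names unknown features or links two features
        within the same tier (ambiguous which to keep).
    """
    tables = [mrm, targeted, untargeted]
    base = set(mrm.sample_ids)
    for t in tables[1:]:
        if set(t.sample_ids) != base:
            raise AlignmentError("tier tables do not share the same sample ids")

    all_ids: list[str] = []
    tier_of: dict[str, str] = {}
    frames = []
    for t in tables:
        dup = set(t.feature_ids) & set(tier_of)
        if dup:
            raise ValidationError(
                f"feature ids shared across tier tables: {sorted(dup)[:5]}; "
                "use identity_map for cross-tier equivalences"
            )
        for fid in t.feature_ids:
            tier_of[fid] = t.tier.loc[fid]
            all_ids.append(fid)
        frames.append(t.intensities.loc[mrm.sample_ids])

    merged = pd.concat(frames, axis=1)

    # union-find over equivalence pairs
    parent = {fid: fid for fid in all_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in identity_map or []:
        for fid in (a, b):
            if fid not in parent:
                raise ValidationError(f"identity_map names unknown feature {fid!r}")
        if tier_of[a] == tier_of[b]:
            raise ValidationError(
                f"identity_map links {a!r} and {b!r} within tier {tier_of[a]!r}"
            )
        parent[find(a)] = find(b)

    classes: dict[str, list[str]] = {}
    for fid in all_ids:
        classes.setdefault(find(fid), []).append(fid)

    order = {fid: i for i, fid in enumerate(all_ids)}
    keep_set = {
        min(members, key=lambda f: (TIER_PRIORITY[tier_of[f]], order[f]))
        for members in classes.values()
    }
    keep = [fid for fid in all_ids if fid in keep_set]  # stable input order

    out = FeatureTable(
        merged.loc[:, keep],
        pd.Series({fid: tier_of[fid] for fid in keep}),
        mrm.batch.loc[mrm.sample_ids],
    )
    return out


# ---------------------------------------------------------------------------
# pH-based pair validation
# ---------------------------------------------------------------------------

@dataclass
class PairValidationResult:
    kept: PairedSampleSet
    removed: list  # rule violations: arterial pH >= venous pH
    excluded_missing_ph: list  # pH not available; counted separately


def validate_pairs(pairs: PairedSampleSet) -> PairValidationResult:
    """Keep subject pairs whose arterial pH is strictly below the venous pH.

    An arterial sample with pH greater than or equal to the venous sample
    indicates a sampling error (the two vessels were likely confused or
    mixed), so the whole pair is removed. Subjects with a missing pH cannot
    be checked and are excluded with a warning, counted separately from
    rule-based removals.
    """
    df = pairs.subjects
    ph_a = pd.to_numeric(df["ph_arterial"], errors="coerce")
    ph_v = pd.to_numeric(df["ph_venous"], errors="coerce")
    missing = ph_a.isna() | ph_v.isna()
    violates = (~missing) & (ph_a >= ph_v)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} subject(s) excluded for missing pH",
            stacklevel=2,
        )
    kept_ids = df.index[~missing & ~violates]
    return PairValidationResult(
        kept=pairs.subset(kept_ids),
        removed=list(df.index[violates]),
        excluded_missing_ph=list(df.index[missing]),
    )


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def clean_nonpositive(table: FeatureTable) -> FeatureTable:
    """Convert zero/negative intensities to missing (log-domain requirement)."""
    vals = table.intensities.to_numpy(dtype=float, copy=True)
    with np.errstate(invalid="ignore"):
        vals[vals <= 0] = np.nan
    out = table.copy()
    out.intensities.iloc[:, :] = vals
    return out


class LowRankImputer:
    """Iterative low-rank completion of missing log2 intensities.

    Missing cells are initialized at per-feature medians; the matrix is then
    alternately approximated by its rank-``n_components`` truncated SVD and
    the missing cells refilled from the approximation, until the relative
    change of the imputed cells falls below ``tol`` or ``max_iter`` is
    reached. Observed cells are never modified.

    This is the latent-projection family of imputation used for metabolomics
    feature tables; with a tiny missing fraction the precise variant is
    immaterial downstream.
    """

    def __init__(self, n_components: int = 3, tol: float = 1e-4, max_iter: int = 50):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def fit_transform(self, log2_matrix: pd.DataFrame) -> pd.DataFrame:
        X = log2_matrix.to_numpy(dtype=float, copy=True)
        mask = np.isnan(X)
        if not mask.any():
            self.n_iter_ = 0
            return log2_matrix.copy()
        empty_feat = mask.all(axis=0)
        if empty_feat.any():
            fid = log2_matrix.columns[empty_feat][0]
            raise UnimputableError(f"feature {fid!r} is entirely missing")
        empty_samp = mask.all(axis=1)
        if empty_samp.any():
            sid = log2_matrix.index[empty_samp][0]
            raise UnimputableError(f"sample {sid!r} is entirely missing")

        med = np.nanmedian(X, axis=0)
        X[mask] = np.take(med, np.nonzero(mask)[1])
        k = min(self.n_components, min(X.shape) - 1) or 1
        prev = X[mask].copy()
        for it in range(1, self.max_iter + 1):
            # column-centered truncated SVD reconstruction
            center = X.mean(axis=0)
            U, s, Vt = np.linalg.svd(X - center, full_matrices=False)
            approx = (U[:, :k] * s[:k]) @ Vt[:k] + center
            X[mask] = approx[mask]
            denom = np.linalg.norm(prev)
            change = np.linalg.norm(X[mask] - prev) / (denom if denom > 0 else 1.0)
            prev = X[mask].copy()
            if change < self.tol:
                break
        self.n_iter_ = it
        out = log2_matrix.copy()
        out.iloc[:, :] = X
        return out


def impute(
    table: FeatureTable,
    n_components: int = 3,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> FeatureTable:
    """Impute missing intensities; observed cells are preserved exactly.

    Works on the log2 scale and back-transforms, so imputed intensities are
    strictly positive. Precondition: missing fraction below 20%.
    """
    frac = table.missing_fraction()
    if frac == 0:
        return table.copy()
    na = table.intensities.isna()
    if na.all(axis=0).any():
        fid = table.feature_ids[na.all(axis=0)][0]
        raise UnimputableError(f"feature {fid!r} is entirely missing")
    if na.all(axis=1).any():
        sid = table.sample_ids[na.all(axis=1)][0]
        raise UnimputableError(f"sample {sid!r} is entirely missing")
    if frac >= 0.20:
        raise UnimputableError(
            f"missing fraction {frac:.1%} too high for low-rank completion"
        )
    log2 = table.log2()
    filled = LowRankImputer(n_components, tol, max_iter).fit_transform(log2)
    out_vals = table.intensities.to_numpy(dtype=float, copy=True)
    mask = np.isnan(out_vals)
    out_vals[mask] = np.exp2(filled.to_numpy())[mask]
    out = table.copy()
    out.intensities.iloc[:, :] = out_vals
    return out


# ---------------------------------------------------------------------------
# batch alignment
# ---------------------------------------------------------------------------

def align_batches(table: FeatureTable, min_batch_size: int = 3) -> FeatureTable:
    """Remove additive per-(feature, batch) offsets by median matching.

    For every feature, each batch's log2 intensities are shifted so that the
    batch median equals the feature's reference median, taken as the median
    over eligible batches of the per-batch medians (this reference makes the
    operation exactly idempotent). Batches with fewer than
    ``min_batch_size`` samples are left unshifted with a warning. A
    single-batch table is returned unchanged.

    The shift is constant within a (feature, batch) cell, so within-batch
    intensity ordering is preserved. Missing cells stay missing.
    """
    batches = table.batch
    labels = pd.unique(batches)
    if len(labels) <= 1:
        return table.copy()

    counts = batches.value_counts()
    small = [b for b in labels if counts[b] < min_batch_size]
    if small:
        warnings.warn(
            f"batch(es) {small} have fewer than {min_batch_size} samples "
            "and were left unshifted",
            stacklevel=2,
        )
    eligible = [b for b in labels if counts[b] >= min_batch_size]
    if not eligible:
        return table.copy()

    log2 = table.log2()
    batch_medians = pd.DataFrame(
        {b: log2.loc[batches[batches == b].index].median(axis=0) for b in eligible}
    )  # features x eligible batches
    reference = batch_medians.median(axis=1)

    out_log2 = log2.copy()
    for b in eligible:
        rows = batches[batches == b].index
        shift = reference - batch_medians[b]
        out_log2.loc[rows] = out_log2.loc[rows].add(shift, axis=1)

    out = table.copy()
    out.intensities.iloc[:, :] = np.exp2(out_log2.to_numpy())
    return out
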