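"""Per-metabolite fold changes, rank/t tests, FDR adjustment, and
replication testing against a prior metabolite list.

Fold changes are geometric means of per-subject or per-group intensity
ratios, coherent with the log2 effect matrix used by the multivariate
model: the paired fold change of a feature is ``2 ** mean(log2(A/V))``.
Which group forms the numerator of a between-group fold change is always an
explicit argument and echoed in the output, never guessed.

P-values come from two-sided tests: the Mann-Whitney U test (exact null
distribution for small tie-free samples, normal approximation with tie
correction otherwise) for between-group comparisons, and the one-sample
paired t-test on effect-matrix columns for the within-subject contrast.
Benjamini-Hochberg step-up adjustment controls the false discovery rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "paired_fold_change",
    "group_fold_change",
    "paired_t_test",
    "mann_whitney_u",
    "benjamini_hochberg",
    "vessel_table",
    "trait_table",
    "replication_test",
]

_TINY_P = float(np.finfo(float).tiny)


def paired_fold_change(
    effect_matrix: pd.DataFrame, features=None, method: str = "geometric"
) -> pd.Series:
    """Per-feature arterial/venous fold change from the effect matrix.

    The default is the geometric mean of per-subject ratios,
    ``FC_j = 2 ** mean_i(e_ij)``, coherent with the log2 effect matrix;
    ``method="arithmetic"`` averages the ratios directly instead. Values
    > 1 mean higher in the arterial sample.
    """
    if effect_matrix.shape[0] == 0:
        raise ValueError("effect matrix has no subjects")
    cols = effect_matrix.columns if features is None else pd.Index(features)
    sub = effect_matrix.loc[:, cols]
    if method == "geometric":
        fc = np.exp2(sub.mean(axis=0))
    elif method == "arithmetic":
        fc = np.exp2(sub).mean(axis=0)
    else:
        raise ValueError("method must be 'geometric' or 'arithmetic'")
    fc.name = "fold_change"
    return fc


def group_fold_change(
    intensities: pd.DataFrame,
    labels: pd.Series,
    numerator,
    denominator,
    features=None,
    method: str = "geometric",
) -> pd.Series:
    """Ratio of mean intensities between two explicitly named groups.

    ``numerator`` and ``denominator`` name the two label levels explicitly;
    the result Series carries them in its ``name`` so the direction is
    unambiguous in any exported table. The default compares geometric
    means; ``method="ratio_of_means"`` compares arithmetic means.
    """
    labels = labels.reindex(intensities.index)
    num_rows = intensities.loc[labels == numerator]
    den_rows = intensities.loc[labels == denominator]
    if len(num_rows) == 0 or len(den_rows) == 0:
        raise ValueError(
            f"empty group: {numerator!r} n={len(num_rows)}, "
            f"{denominator!r} n={len(den_rows)}"
        )
    cols = intensities.columns if features is None else pd.Index(features)
    if method == "geometric":
        gm_num = np.log2(num_rows.loc[:, cols]).mean(axis=0)
        gm_den = np.log2(den_rows.loc[:, cols]).mean(axis=0)
        fc = np.exp2(gm_num - gm_den)
    elif method == "ratio_of_means":
        fc = num_rows.loc[:, cols].mean(axis=0) / den_rows.loc[:, cols].mean(axis=0)
    else:
        raise ValueError("method must be 'geometric' or 'ratio_of_means'")
    fc.name = f"fold_change[{numerator}/{denominator}]"
    return fc


def paired_t_test(effect_column) -> tuple[float, bool]:
    """Two-sided one-sample t-test of an effect-matrix column against zero.

    Returns ``(p, degenerate)``. A zero-variance column is degenerate: its
    p-value is 1 when the common value is zero (no effect, no evidence) and
    the smallest positive float otherwise (the t statistic diverges).
    """
    x = np.asarray(effect_column, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValueError("paired t-test needs >= 3 finite values")
    if np.ptp(x) == 0:
        return (1.0 if x[0] == 0 else _TINY_P), True
    res = stats.ttest_1samp(x, 0.0)
    return float(res.pvalue), False


def mann_whitney_u(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Uses the exact null distribution when the smaller sample has at most 8
    observations and there are no ties; otherwise the normal approximation
    with tie correction. Two identical samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def _finish_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["p_fdr"] = benjamini_hochberg(df["p_unadjusted"].to_numpy())
    order = np.argsort(-np.abs(np.log2(df["fold_change"].to_numpy())), kind="stable")
    return df.iloc[order]

def vessel_table(
    effect_matrix: pd.DataFrame,
    table_log2: pd.DataFrame,
    arterial_samples,
    venous_samples,
    features,
    annotations: pd.Series | None = None,
) -> pd.DataFrame:
    """Arteriovenous metabolite table: fold change, tests, FDR.

    One row per feature in ``features``: the paired (geometric mean) fold
    change arterial/venous, the two-sided Mann-Whitney U p-value comparing
    arterial and venous samples as two groups (the convention of published
    arteriovenous tables; ``p_unadjusted``/``p_fdr``), and the paired
    t-test on the log2 ratios as a side-by-side column (``p_paired_t``).
    The two tests answer slightly different questions for paired data; both
    are reported. Rows are sorted by |log2 FC| descending.
    """
    features = pd.Index(features)
    fc = paired_fold_change(effect_matrix, features)
    rows = []
    for f in features:
        p_mw = mann_whitney_u(
            table_log2.loc[arterial_samples, f], table_log2.loc[venous_samples, f]
        )
        p_t, degen = paired_t_test(effect_matrix[f])
        rows.append(
            {
                "metabolite": f,
                "fold_change": float(fc[f]),
                "p_unadjusted": p_mw,
                "p_paired_t": p_t,
                "degenerate_t": degen,
                "direction": "arterial" if fc[f] > 1 else "venous",
                "category": None if annotations is None else annotations.get(f),
            }
        )
    return _finish_table(pd.DataFrame(rows)).reset_index(drop=True)


def trait_table(
    intensities: pd.DataFrame,
    labels: pd.Series,
    numerator,
    denominator,
    features,
    annotations: pd.Series | None = None,
) -> pd.DataFrame:
    """Dichotomous-trait metabolite table (fold change, Mann-Whitney, FDR)."""
    features = pd.Index(features)
    fc = group_fold_change(intensities, labels, numerator, denominator, features)
    labels = labels.reindex(intensities.index)
    rows = []
    for f in features:
        p = mann_whitney_u(
            np.log2(intensities.loc[labels == numerator, f]),
            np.log2(intensities.loc[labels == denominator, f]),
        )
        rows.append(
            {
                "metabolite": f,
                "fold_change": float(fc[f]),
                "p_unadjusted": p,
                "direction": numerator if fc[f] > 1 else denominator,
                "category": None if annotations is None else annotations.get(f),
            }
        )
    out = _finish_table(pd.DataFrame(rows)).reset_index(drop=True)
    out.attrs["numerator"] = numerator
    out.attrs["denominator"] = denominator
    return out


def replication_test(
    intensities: pd.DataFrame,
    labels: pd.Series,
    prior: pd.DataFrame,
    numerator,
    denominator,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test previously reported trait-associated metabolites in new data.

    ``prior`` needs columns ``metabolite`` and ``direction`` (``"up"`` if
    the metabolite was previously higher in the ``numerator`` group,
    ``"down"`` otherwise). A finding replicates when the unadjusted
    Mann-Whitney p-value is below ``alpha`` *and* the fold-change direction
    matches. Metabolites absent from the current data are reported with
    status ``"not measured"`` rather than raising.
    """
    if len(prior) == 0:
        raise ValueError("empty prior metabolite list")
    labels = labels.reindex(intensities.index)
    rows = []
    for _, rec in prior.iterrows():
        m = rec["metabolite"]
        if m not in intensities.columns:
            rows.append(
                {
                    "metabolite": m,
                    "fold_change": np.nan,
                    "p_unadjusted": np.nan,
                    "expected_direction": rec["direction"],
                    "replicated": False,
                    "status": "not measured",
                }
            )
            continue
        fc = float(
            group_fold_change(intensities, labels, numerator, denominator, [m]).iloc[0]
        )
        p = mann_whitney_u(
            np.log2(intensities.loc[labels == numerator, m]),
            np.log2(intensities.loc[labels == denominator, m]),
        )
        direction = "up" if fc > 1 else "down"
        replicated = (p < alpha) and (direction == rec["direction"])
        rows.append(
            {
                "metabolite": m,
                "fold_change": fc,
                "p_unadjusted": p,
                "expected_direction": rec["direction"],
                "replicated": bool(replicated),
                "status": "tested",
            }
        )
    return pd.DataFrame(rows)
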