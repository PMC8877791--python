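"""Effect-matrix construction for multilevel (within-subject) analysis.

A paired arterial/venous comparison is turned into a classification problem
by first isolating the within-subject contrast

    e_ij = log2(arterial_ij / venous_ij)

(the *effect matrix*: subjects x features, between-subject baselines cancel)
and then stacking the effect matrix on top of its negation. The stacked
design is modeled against a target vector of -1 for the top block and +1
for the bottom block, so the decision boundary for predictions sits at
zero, and the two rows of a subject always travel together through
cross-validation via a shared group id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureTable, PairedSampleSet

__all__ = ["build_effect_matrix", "build_design", "MultilevelDesign"]


class PairingError(ValueError):
    """A subject's arterial or venous sample is absent from the table."""


def build_effect_matrix(
    table: FeatureTable, pairs: PairedSampleSet
) -> pd.DataFrame:
    """Per-subject log2(arterial / venous) intensity ratios.

    ``table`` must be fully imputed (no missing cells) with strictly
    positive intensities. Returns a subjects x features DataFrame aligned
    with ``pairs.subject_ids``.
    """
    art_ids = pairs.subjects["arterial_sample"]
    ven_ids = pairs.subjects["venous_sample"]
    for sid, samp in pd.concat([art_ids, ven_ids]).items():
        if samp not in table.sample_ids:
            raise PairingError(f"sample {samp!r} of subject {sid!r} not in table")
    log2 = table.log2()
    if log2.isna().to_numpy().any():
        raise PairingError("table contains missing values; impute first")
    arterial = log2.loc[art_ids].to_numpy()
    venous = log2.loc[ven_ids].to_numpy()
    return pd.DataFrame(
        arterial - venous,
        index=pairs.subject_ids.copy(),
        columns=table.feature_ids.copy(),
    )


@dataclass
class MultilevelDesign:
    """Antisymmetric augmentation of an effect matrix.

    ``X`` stacks the effect matrix E on top of -E; ``y`` is -1 for the E
    block and +1 for the -E block; ``groups`` assigns each subject's two
    rows the same id so grouped cross-validation never separates them.
    The ``flip_coding`` flag of :func:`build_design` reverses the class
    orientation.
    """

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.X) // 2
        top = self.X.iloc[:n].to_numpy()
        bottom = self.X.iloc[n:].to_numpy()
        if not np.array_equal(top, -bottom):
            raise ValueError("bottom block is not the exact negation of the top")
        if int(self.y.sum()) != 0:
            raise ValueError("targets do not sum to zero")


def build_design(effect_matrix: pd.DataFrame, flip_coding: bool = False) -> MultilevelDesign:
    """Stack an effect matrix with its negation into a classification design.

    By default the arterial-over-venous block is coded -1 and its mirror +1;
    ``flip_coding=True`` reverses the convention. Class assignment is purely
    a labeling choice and does not affect downstream classification rates.
    """
    E = effect_matrix.to_numpy(dtype=float)
    if not np.isfinite(E).all():
        raise ValueError("effect matrix contains non-finite values")
    n = E.shape[0]
    subjects = effect_matrix.index.to_numpy()
    X = pd.DataFrame(
        np.vstack([E, -E]),
        index=[f"{s}:+" for s in subjects] + [f"{s}:-" for s in subjects],
        columns=effect_matrix.columns.copy(),
    )
    sign = 1 if flip_coding else -1
    y = np.concatenate([np.full(n, sign), np.full(n, -sign)]).astype(float)
    groups = np.concatenate([np.arange(n), np.arange(n)])
    return MultilevelDesign(X=X, y=y, groups=groups)
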