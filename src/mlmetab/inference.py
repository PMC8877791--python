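"""Permutation significance testing and the a-priori performance gate.

Only models that clear an a-priori performance threshold (Q2 > 0.2 or
classification rate > 66%) are subjected to permutation testing; the gate
keeps the expensive permutation step away from models that show no
predictive ability in the first place.

The permutation null respects the study design:

* **multilevel** (paired within-subject) designs are permuted by
  independently flipping the sign of each subject's effect row together
  with its mirrored row — the exchangeability-preserving analogue of
  swapping the two vessel labels within a subject;
* **between-subject** (trait) designs permute the trait labels across
  subjects.

P-values use the add-one estimator ``p = (1 + #{null >= observed}) /
(1 + n_perm)``, which is strictly positive and valid for any number of
random permutations; the raw proportion is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PermutationResult",
    "permutation_test",
    "performance_gate",
    "signflip_permute",
    "label_permute",
]


class GateError(ValueError):
    """Unknown fitness kind passed to the performance gate."""


@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    p_value: float
    p_raw: float
    n_perm: int
    seed: int | None
    scheme: str

    def as_dict(self) -> dict:
        return {
            "observed": float(self.observed),
            "p_value": float(self.p_value),
            "p_raw": float(self.p_raw),
            "n_perm": int(self.n_perm),
            "scheme": self.scheme,
            "null_mean": float(np.mean(self.null_values)),
            "null_values": [float(v) for v in self.null_values],
        }


def signflip_permute(X, y, groups, rng):
    """Randomly negate each group's mirrored row pair (vessel-label swap)."""
    groups = np.asarray(groups)
    Xp = np.array(X, dtype=float, copy=True)
    for g in np.unique(groups):
        if rng.random() < 0.5:
            rows = np.flatnonzero(groups == g)
            Xp[rows] = -Xp[rows]
    return Xp, np.asarray(y, dtype=float), groups


def label_permute(X, y, groups, rng):
    """Permute targets across observations (between-subject designs)."""
    y = np.asarray(y)
    perm = rng.permutation(len(y))
    return np.asarray(X, dtype=float), y[perm], groups


_SCHEMES = {"signflip": signflip_permute, "labels": label_permute}


def permutation_test(
    fit_fn,
    X,
    y,
    groups=None,
    n_perm: int = 1000,
    seed: int | None = None,
    scheme: str = "labels",
) -> PermutationResult:
    """Permutation test of a modeling procedure's fitness.

    ``fit_fn(X, y, groups, seed) -> float`` must return the model fitness
    (larger is better) and be deterministic given its seed. The observed
    fitness is computed with the same procedure and seeding scheme as the
    null fits, so observed and null values are exchangeable under the null
    hypothesis.

    Parameters
    ----------
    scheme : {"labels", "signflip"}
        "labels" permutes ``y`` across observations; "signflip" negates
        random subjects' mirrored row pairs (use for multilevel designs).
    n_perm : int
        Number of random permutations; at least 20 (below that the
        resolution of the add-one p-value is too coarse to be useful).
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for a usable p-value resolution")
    if scheme not in _SCHEMES:
        raise ValueError(f"scheme must be one of {sorted(_SCHEMES)}")
    if scheme == "signflip" and groups is None:
        raise ValueError("signflip permutation requires group ids")
    permute = _SCHEMES[scheme]

    root = np.random.SeedSequence(seed if seed is not None else 0)
    fit_seeds = root.spawn(n_perm + 1)
    rng_perm = np.random.default_rng(root.spawn(n_perm + 2)[-1])

    def run(Xi, yi, gi, ss):
        return float(fit_fn(Xi, yi, gi, int(ss.generate_state(1)[0] % 2**31)))

    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    observed = run(Xa, ya, groups, fit_seeds[0])
    null_values = np.empty(n_perm)
    for i in range(n_perm):
        Xp, yp, gp = permute(Xa, ya, groups, rng_perm)
        null_values[i] = run(Xp, yp, gp, fit_seeds[i + 1])

    n_ge = int(np.sum(null_values >= observed))
    return PermutationResult(
        observed=observed,
        null_values=null_values,
        p_value=(1 + n_ge) / (1 + n_perm),
        p_raw=n_ge / n_perm,
        n_perm=n_perm,
        seed=seed,
        scheme=scheme,
    )


def performance_gate(
    fitness_kind: str,
    value: float,
    q2_threshold: float = 0.2,
    cr_threshold: float = 0.66,
) -> bool:
    """A-priori gate for potentially predictive models.

    Pass iff Q2 > 0.2 or classification rate > 0.66 (strict inequalities;
    thresholds configurable). Only passing models are worth permutation
    testing.
    """
    if not np.isfinite(value):
        raise GateError("fitness value must be finite")
    if fitness_kind == "q2":
        return bool(value > q2_threshold)
    if fitness_kind == "classification_rate":
        return bool(value > cr_threshold)
    raise GateError(f"unknown fitness kind {fitness_kind!r}")
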