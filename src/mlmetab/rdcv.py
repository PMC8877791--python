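"""Repeated double cross-validated random forest with recursive variable
elimination.

This is the modeling engine for both the within-subject (multilevel) vessel
contrast and the between-subject trait models. The procedure:

* **Outer loop** — observations (grouped: a subject's mirrored rows always
  stay together) are split into ``n_outer`` folds; each fold in turn is held
  out entirely and never touches model selection.
* **Inner loop** — on the remaining observations an ``n_inner``-fold CV is
  run while variables are recursively eliminated: after each round variables
  are ranked by mean forest importance and only ``ceil(var_ratio * p)``
  survive, tracking inner validation fitness versus variable count.
* From the inner fitness curve three model sizes are kept: ``min`` (fewest
  variables within tolerance of the optimum), ``max`` (most variables within
  tolerance) and ``mid`` (rounded geometric mean of the two). Models of each
  size are refit on the full outer-training set and predict the held-out
  fold.
* The whole double CV is repeated ``n_rep`` times with fresh fold
  partitions; the final prediction of an observation is the average of its
  out-of-fold predictions across repetitions.

Classification is performed by regressing forests onto +/-1 targets with the
decision boundary at zero, so predictions are continuous and the multilevel
sign-symmetry of paired designs is preserved exactly: the two mirrored rows
of a subject always receive exactly opposite predictions.

Fitness is either the **classification rate** (fraction of observations
whose averaged prediction falls on the correct side of zero; a prediction of
exactly zero counts as misclassified) or **Q2** (1 - PRESS/TSS on averaged
out-of-fold predictions; <= 0 means no predictive ability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

__all__ = [
    "RandomForestRdCV",
    "RdcvResult",
    "classification_rate",
    "q2_score",
    "fit_rdcv",
]

FITNESS_KINDS = ("classification_rate", "q2")


def classification_rate(pred, y) -> float:
    """Fraction of observations predicted on the correct side of zero.

    ``pred`` are continuous predictions, ``y`` the +/-1 targets. A
    prediction of exactly zero sits on the decision boundary and is counted
    as misclassified.
    """
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    if pred.shape != y.shape:
        raise ValueError("pred and y have different lengths")
    return float(np.mean(pred * y > 0))


def q2_score(pred, y) -> float:
    """Predictive Q2 = 1 - sum((y - pred)^2) / sum((y - mean(y))^2)."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero-variance target; Q2 undefined")
    return 1.0 - float(np.sum((y - pred) ** 2)) / tss


@dataclass
class RdcvResult:
    """Everything the repeated double CV produced.

    ``oof_per_rep[size]`` holds one out-of-fold prediction per *unit* (a
    unit is a subject pair in multilevel designs, otherwise one row) and
    repetition; ``row_predictions[size]`` maps these back to the rows of the
    input design. ``fitness`` is computed on the averaged predictions.
    """

    unit_ids: np.ndarray
    y_units: np.ndarray
    fitness_kind: str
    oof_per_rep: dict  # size -> (n_rep, n_units)
    oof_mean: dict  # size -> (n_units,)
    row_predictions: dict  # size -> (n_rows,) aligned with input X
    row_targets: np.ndarray
    fitness: dict  # size -> float
    n_features: dict  # size -> int (rounded mean over rep x outer)
    selected: dict  # size -> list of feature names
    ranks: pd.Series  # average elimination rank per feature (1 = best)
    fitness_curve: pd.DataFrame  # columns: count, fitness (mean inner CV)
    fold_assignments: np.ndarray  # (n_rep, n_units) outer fold index
    size_counts: dict  # size -> list of per-(rep, outer) counts
    multilevel: bool = False
    params: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "fitness_kind": self.fitness_kind,
            "fitness": {k: float(v) for k, v in self.fitness.items()},
            "n_features": {k: int(v) for k, v in self.n_features.items()},
            "selected_mid": list(self.selected["mid"]),
            "multilevel": self.multilevel,
            "params": self.params,
        }


class RandomForestRdCV(BaseEstimator):
    """Random-forest repeated double CV with recursive variable elimination.

    Parameters
    ----------
    n_rep : int
        Number of repetitions of the double CV (fresh fold partitions each).
    n_outer : int
        Outer folds (>= 3).
    n_inner : int or None
        Inner folds; defaults to ``n_outer - 1``.
    var_ratio : float
        Fraction of variables kept per elimination round, in [0.5, 1).
    min_features : int
        Floor for the elimination; if >= the number of input features the
        inner elimination loop is skipped and min = mid = max = all
        features.
    n_trees : int
        Forest size for every fit. Odd by default so that averaged +/-1
        leaf votes cannot land exactly on the zero decision boundary
        (boundary predictions count as misclassified).
    max_features : float
        Fraction of variables tried per split (regression-forest default
        1/3).
    fitness : {"classification_rate", "q2"}
        Model fitness. Classification requires +/-1 targets.
    fitness_tol : float
        Relative band below the optimal inner fitness within which a
        variable count still qualifies for the min/max models.
    importance : {"impurity", "permutation"}
        Variable ranking signal; permutation importance is less biased but
        markedly slower.
    random_state : int or None
        Seed for the full procedure; same seed, same result, bit for bit.

    Attributes
    ----------
    result_ : RdcvResult
    fitness_ : float
        Mid-model fitness on averaged out-of-fold predictions.
    predictions_ : ndarray
        Averaged out-of-fold prediction per input row (mid model).
    selected_min_, selected_mid_, selected_max_ : list of str
    ranks_ : pandas.Series
    """

    def __init__(
        self,
        n_rep: int = 5,
        n_outer: int = 6,
        n_inner: int | None = None,
        var_ratio: float = 0.75,
        min_features: int = 2,
        n_trees: int = 151,
        max_features: float = 1 / 3,
        fitness: str = "classification_rate",
        fitness_tol: float = 0.05,
        importance: str = "impurity",
        fit_final_model: bool = True,
        random_state: int | None = None,
    ):
        self.n_rep = n_rep
        self.n_outer = n_outer
        self.n_inner = n_inner
        self.var_ratio = var_ratio
        self.min_features = min_features
        self.n_trees = n_trees
        self.max_features = max_features
        self.fitness = fitness
        self.fitness_tol = fitness_tol
        self.importance = importance
        self.fit_final_model = fit_final_model
        self.random_state = random_state

    # -- helpers -------------------------------------------------------------

    def _fitness_fn(self):
        return classification_rate if self.fitness == "classification_rate" else q2_score

    def _unit_fitness(self, pred_units, t_units, multilevel):
        """Fitness with multilevel units expanded back to mirrored rows."""
        fn = self._fitness_fn()
        if multilevel:
            pred = np.concatenate([pred_units, -pred_units])
            y = np.concatenate([t_units, -t_units])
            return fn(pred, y)
        return fn(pred_units, t_units)

    @staticmethod
    def _canonicalize(X, y, groups):
        """Collapse a signed-pair (multilevel) design to canonical units.

        Returns ``(Xu, tu, row_of_unit, row_sign, multilevel)``. For a
        multilevel design each group's two mirrored rows are represented by
        the orientation whose first nonzero entry is positive; this makes
        the internal representation identical whichever vessel labeling the
        caller used, so label swaps negate predictions bitwise.
        """
        if groups is None:
            return X, y, None, None, False
        groups = np.asarray(groups)
        uniq, inv = np.unique(groups, return_inverse=True)
        rows_of = [np.flatnonzero(inv == g) for g in range(len(uniq))]
        if any(len(r) != 2 for r in rows_of):
            return X, y, None, None, False
        for r in rows_of:
            if not (np.array_equal(X[r[0]], -X[r[1]]) and y[r[0]] == -y[r[1]]):
                return X, y, None, None, False
        n_units = len(uniq)
        p = X.shape[1]
        Xu = np.empty((n_units, p))
        tu = np.empty(n_units)
        row_sign = np.empty(X.shape[0])
        for g, r in enumerate(rows_of):
            x1 = X[r[0]]
            nz = np.flatnonzero(x1)
            s = 1.0 if (len(nz) == 0 or x1[nz[0]] > 0) else -1.0
            Xu[g] = s * x1
            tu[g] = y[r[0]] if s > 0 else y[r[1]]
            row_sign[r[0]] = s
            row_sign[r[1]] = -s
        return Xu, tu, rows_of, row_sign, True

    def _training_rows(self, Xu, tu, idx, multilevel, feats):
        """Design rows for the units ``idx`` (both orientations if multilevel)."""
        if multilevel:
            Xtr = np.vstack([Xu[np.ix_(idx, feats)], -Xu[np.ix_(idx, feats)]])
            ytr = np.concatenate([tu[idx], -tu[idx]])
        else:
            Xtr = Xu[np.ix_(idx, feats)]
            ytr = tu[idx]
        return Xtr, ytr

    def _make_folds(self, rng, tu, idx, n_folds, multilevel):
        """Assign the units in ``idx`` to ``n_folds`` folds.

        Classification folds are stratified per class (shuffle within class,
        deal round-robin); regression folds use systematic sampling over the
        sorted response. Multilevel designs need no stratification because
        every training set contains both orientations of each unit.
        """
        idx = np.asarray(idx)
        assignment = np.empty(len(idx), dtype=int)
        if multilevel or self.fitness == "classification_rate":
            if multilevel:
                order = rng.permutation(len(idx))
                assignment[order] = np.arange(len(idx)) % n_folds
            else:
                assignment[:] = -1
                start = rng.integers(n_folds)
                for cls in np.unique(tu[idx]):
                    members = np.flatnonzero(tu[idx] == cls)
                    members = members[rng.permutation(len(members))]
                    assignment[members] = (np.arange(len(members)) + start) % n_folds
        else:
            order = np.argsort(tu[idx], kind="stable")
            pos = 0
            fold_seq = np.empty(len(idx), dtype=int)
            while pos < len(idx):
                block = order[pos : pos + n_folds]
                labels = rng.permutation(n_folds)[: len(block)]
                fold_seq[block] = labels
                pos += n_folds
            assignment = fold_seq
        return [idx[assignment == f] for f in range(n_folds)]

    def _forest(self, seed) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            random_state=int(seed),
            n_jobs=1,
        )

    def _importance(self, forest, Xval, yval, rng):
        if self.importance == "impurity":
            return forest.feature_importances_
        res = permutation_importance(
            forest, Xval, yval, n_repeats=5,
            random_state=int(rng.integers(2**31)),
        )
        return res.importances_mean

    # -- main ----------------------------------------------------------------

    def fit(self, X, y, groups=None) -> "RandomForestRdCV":
        feature_names = (
            list(X.columns) if isinstance(X, pd.DataFrame) else None
        )
        Xarr = np.asarray(X, dtype=float)
        yarr = np.asarray(y, dtype=float).ravel()
        if Xarr.ndim != 2 or len(Xarr) != len(yarr):
            raise ValueError("X must be 2d with one target per row")
        if not np.isfinite(Xarr).all():
            raise ValueError("X contains non-finite values; impute first")
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(Xarr.shape[1])]
        if self.fitness not in FITNESS_KINDS:
            raise ValueError(f"fitness must be one of {FITNESS_KINDS}")
        if self.n_outer < 3:
            raise ValueError("n_outer must be >= 3")
        if not 0.5 <= self.var_ratio < 1:
            raise ValueError("var_ratio must be in [0.5, 1)")
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if self.fitness == "classification_rate":
            classes = np.unique(yarr)
            if not np.array_equal(classes, [-1.0, 1.0]):
                raise ValueError(
                    "classification requires both target classes coded -1/+1"
                )
        else:
            if np.ptp(yarr) == 0:
                raise ValueError("zero-variance continuous target")

        Xu, tu, rows_of, row_sign, multilevel = self._canonicalize(
            Xarr, yarr, groups
        )
        if groups is not None and not multilevel:
            # general grouped design: one unit per group is unsupported
            # unless groups are simple row ids
            groups_arr = np.asarray(groups)
            if len(np.unique(groups_arr)) != len(groups_arr):
                raise ValueError(
                    "grouped designs are supported only as mirrored "
                    "(multilevel) pairs or one row per group"
                )
        n_units, p = Xu.shape
        n_inner = self.n_inner if self.n_inner is not None else self.n_outer - 1
        if n_inner < 2:
            raise ValueError("n_inner must be >= 2")
        if n_units < 2 * self.n_outer:
            raise ValueError(
                f"{n_units} units cannot give >= 2 observations per outer fold"
            )
        eliminate = self.min_features < p

        root = np.random.SeedSequence(
            self.random_state if self.random_state is not None else 0
        )
        rep_seeds = root.spawn(self.n_rep)

        sizes = ("min", "mid", "max")
        oof = {s: np.full((self.n_rep, n_units), np.nan) for s in sizes}
        counts: dict[str, list[int]] = {s: [] for s in sizes}
        sel_freq: dict[str, np.ndarray] = {s: np.zeros(p) for s in sizes}
        rank_sum = np.zeros(p)
        rank_n = 0
        curve_acc: dict[int, list[float]] = {}
        fold_assign = np.empty((self.n_rep, n_units), dtype=int)

        for rep in range(self.n_rep):
            rng = np.random.default_rng(rep_seeds[rep])
            outer_folds = self._make_folds(
                rng, tu, np.arange(n_units), self.n_outer, multilevel
            )
            for f, members in enumerate(outer_folds):
                fold_assign[rep, members] = f
            for outer_idx, test_units in enumerate(outer_folds):
                train_units = np.concatenate(
                    [m for i, m in enumerate(outer_folds) if i != outer_idx]
                )
                if eliminate:
                    path, ranks = self._eliminate(
                        rng, Xu, tu, train_units, n_inner, multilevel
                    )
                    rank_sum += ranks
                    rank_n += 1
                    for count, fit_val, _ in path:
                        curve_acc.setdefault(count, []).append(fit_val)
                    chosen = self._pick_sizes(path)
                else:
                    feats = np.arange(p)
                    chosen = {s: feats for s in sizes}
                refit_cache: dict[bytes, np.ndarray] = {}
                for s in sizes:
                    feats = chosen[s]
                    counts[s].append(len(feats))
                    sel_freq[s][feats] += 1
                    key = feats.tobytes()
                    if key not in refit_cache:  # min/mid/max may coincide
                        Xtr, ytr = self._training_rows(
                            Xu, tu, train_units, multilevel, feats
                        )
                        forest = self._forest(rng.integers(2**31))
                        forest.fit(Xtr, ytr)
                        refit_cache[key] = forest.predict(
                            Xu[np.ix_(test_units, feats)]
                        )
                    oof[s][rep, test_units] = refit_cache[key]

        oof_mean = {s: oof[s].mean(axis=0) for s in sizes}
        fitness = {
            s: self._unit_fitness(oof_mean[s], tu, multilevel) for s in sizes
        }
        n_feat = {s: int(round(float(np.mean(counts[s])))) for s in sizes}
        if rank_n:
            avg_rank = rank_sum / rank_n
        else:
            avg_rank = np.full(p, (p + 1) / 2.0)
        ranks = pd.Series(avg_rank, index=feature_names, name="avg_rank")
        selected = {}
        for s in sizes:
            order = np.lexsort((np.arange(p), avg_rank, -sel_freq[s]))
            selected[s] = [feature_names[j] for j in order[: n_feat[s]]]

        if multilevel:
            row_pred = {}
            for s in sizes:
                rp = np.empty(len(Xarr))
                for g, r in enumerate(rows_of):
                    rp[r[0]] = row_sign[r[0]] * oof_mean[s][g] * 1.0
                    rp[r[1]] = -rp[r[0]]
                row_pred[s] = rp
            row_targets = yarr
        else:
            row_pred = {s: oof_mean[s].copy() for s in sizes}
            row_targets = tu

        curve = pd.DataFrame(
            sorted(
                ((c, float(np.mean(v))) for c, v in curve_acc.items()),
                reverse=True,
            ),
            columns=["count", "fitness"],
        )

        self.result_ = RdcvResult(
            unit_ids=np.arange(n_units),
            y_units=tu,
            fitness_kind=self.fitness,
            oof_per_rep=oof,
            oof_mean=oof_mean,
            row_predictions=row_pred,
            row_targets=row_targets,
            fitness=fitness,
            n_features=n_feat,
            selected=selected,
            ranks=ranks,
            fitness_curve=curve,
            fold_assignments=fold_assign,
            size_counts=counts,
            multilevel=multilevel,
            params=self.get_params(),
        )
        self.fitness_ = fitness["mid"]
        self.predictions_ = row_pred["mid"]
        self.selected_min_ = selected["min"]
        self.selected_mid_ = selected["mid"]
        self.selected_max_ = selected["max"]
        self.ranks_ = ranks
        self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        self.n_features_in_ = p

        if self.fit_final_model:
            # final consensus forest at the mid selection, for predict()
            mid_idx = [feature_names.index(f) for f in selected["mid"]]
            rng_final = np.random.default_rng(root.spawn(self.n_rep + 1)[-1])
            Xtr, ytr = self._training_rows(
                Xu, tu, np.arange(n_units), multilevel,
                np.asarray(mid_idx, dtype=int),
            )
            self.final_model_ = self._forest(rng_final.integers(2**31)).fit(Xtr, ytr)
            self._final_features_ = mid_idx
        return self

    # -- inner elimination ---------------------------------------------------

    def _eliminate(self, rng, Xu, tu, train_units, n_inner, multilevel):
        """Recursive variable elimination under inner CV.

        Returns the elimination path ``[(count, inner fitness, feature
        indices), ...]`` (descending counts) and a full elimination rank per
        feature (1 = survived longest / most important).
        """
        p = Xu.shape[1]
        feats = np.arange(p)
        ranks = np.zeros(p)
        inner_folds = self._make_folds(rng, tu, train_units, n_inner, multilevel)
        path = []
        while True:
            preds = np.empty(len(train_units))
            pos_of = {u: i for i, u in enumerate(train_units)}
            imp = np.zeros(len(feats))
            for fold_units in inner_folds:
                fit_units = np.setdiff1d(train_units, fold_units)
                Xtr, ytr = self._training_rows(
                    Xu, tu, fit_units, multilevel, feats
                )
                forest = self._forest(rng.integers(2**31))
                forest.fit(Xtr, ytr)
                Xval = Xu[np.ix_(fold_units, feats)]
                preds[[pos_of[u] for u in fold_units]] = forest.predict(Xval)
                imp += self._importance(forest, Xval, tu[fold_units], rng)
            imp /= len(inner_folds)
            fit_val = self._unit_fitness(preds, tu[train_units], multilevel)
            path.append((len(feats), fit_val, feats.copy()))
            # stable ranking: importance descending, feature index ascending
            order = np.lexsort((feats, -imp))
            if len(feats) <= self.min_features:
                ranks[feats[order]] = np.arange(1, len(feats) + 1)
                break
            nxt = max(
                self.min_features,
                min(len(feats) - 1, math.ceil(self.var_ratio * len(feats))),
            )
            dropped = feats[order[nxt:]]
            ranks[dropped] = np.arange(nxt + 1, len(feats) + 1)
            feats = np.sort(feats[order[:nxt]])
        return path, ranks

    def _pick_sizes(self, path):
        """min/mid/max variable counts within tolerance of the inner optimum."""
        counts = np.array([c for c, _, _ in path])
        fits = np.array([f for _, f, _ in path])
        best = fits.max()
        thr = best - self.fitness_tol * abs(best)
        ok = np.flatnonzero(fits >= thr - 1e-12)
        cmin = counts[ok].min()
        cmax = counts[ok].max()
        cmid_target = math.sqrt(cmin * cmax)
        # snap to the nearest count on the elimination path
        cmid = int(counts[np.argmin(np.abs(counts - cmid_target))])
        by_count = {c: feats for c, _, feats in path}
        return {"min": by_count[cmin], "mid": by_count[cmid], "max": by_count[cmax]}

    # -- prediction ----------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Predict with the final consensus forest (mid-size variable set)."""
        if not hasattr(self, "final_model_"):
            raise ValueError("estimator is not fitted")
        Xarr = np.asarray(X, dtype=float)
        return self.final_model_.predict(Xarr[:, self._final_features_])


def fit_rdcv(X, y, groups=None, **params) -> RdcvResult:
    """Functional wrapper: fit a :class:`RandomForestRdCV` and return its result."""
    model = RandomForestRdCV(**params)
    model.fit(X, y, groups=groups)
    return model.result_
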