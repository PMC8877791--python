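"""Fold changes, univariate tests, FDR adjustment, replication."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mlmetab import (
    benjamini_hochberg,
    group_fold_change,
    mann_whitney_u,
    paired_fold_change,
    paired_t_test,
    replication_test,
)
from mlmetab.univariate import trait_table, vessel_table


def _E(cols):
    return pd.DataFrame({f"f{i}": c for i, c in enumerate(cols)})


class TestFoldChange:
    def test_constant_ratio(self):
        E = _E([[1.0, 1.0, 1.0]])
        assert paired_fold_change(E).iloc[0] == pytest.approx(2.0)

    def test_symmetric_column_cancels(self):
        E = _E([[1.0, -1.0]])
        assert paired_fold_change(E).iloc[0] == pytest.approx(1.0)

    def test_direct_computation(self):
        E = _E([[1.0, 1.0, 0.0]])
        assert paired_fold_change(E).iloc[0] == pytest.approx(2 ** (2 / 3))
        assert paired_fold_change(E).iloc[0] == pytest.approx(1.5874, abs=1e-4)

    def test_reciprocal_under_negation(self):
        rng = np.random.default_rng(0)
        E = pd.DataFrame(rng.normal(size=(10, 6)))
        fc = paired_fold_change(E)
        fc_neg = paired_fold_change(-E)
        np.testing.assert_allclose(fc * fc_neg, 1.0, rtol=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            paired_fold_change(pd.DataFrame(columns=["f0"]))

    def test_group_fc_identical_groups(self):
        df = pd.DataFrame({"f0": [2.0, 3.0, 2.0, 3.0]}, index=list("abcd"))
        labels = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        assert group_fold_change(df, labels, "x", "y").iloc[0] == pytest.approx(1.0)

    def test_group_fc_uniform_doubling(self):
        df = pd.DataFrame({"f0": [2.0, 4.0, 1.0, 2.0]}, index=list("abcd"))
        labels = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        assert group_fold_change(df, labels, "x", "y").iloc[0] == pytest.approx(2.0)

    def test_group_fc_geometric_means(self):
        # num = (1, 4), den = (2, 2): geometric means both 2 -> FC = 1
        df = pd.DataFrame({"f0": [1.0, 4.0, 2.0, 2.0]}, index=list("abcd"))
        labels = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        fc = group_fold_change(df, labels, "x", "y")
        assert fc.iloc[0] == pytest.approx(1.0)
        assert fc.name == "fold_change[x/y]"  # direction echoed, never guessed

    def test_group_fc_empty_group_raises(self):
        df = pd.DataFrame({"f0": [1.0, 2.0]}, index=list("ab"))
        labels = pd.Series(["x", "x"], index=list("ab"))
        with pytest.raises(ValueError, match="empty group"):
            group_fold_change(df, labels, "x", "y")


class TestPairedT:
    def test_zero_column_degenerate_p_one(self):
        p, degenerate = paired_t_test([0.0, 0.0, 0.0, 0.0])
        assert p == 1.0 and degenerate

    def test_constant_nonzero_column(self):
        p, degenerate = paired_t_test([1.0, 1.0, 1.0, 1.0])
        assert degenerate and p < 0.05

    def test_matches_textbook_formula(self):
        x = np.array([0.5, 1.0, 1.5])
        t = x.mean() / (x.std(ddof=1) / np.sqrt(3))
        p_expected = 2 * stats.t.sf(abs(t), df=2)
        p, degenerate = paired_t_test(x)
        assert not degenerate
        assert p == pytest.approx(p_expected, rel=1e-12)

    def test_needs_three_values(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0])


class TestMannWhitney:
    def test_extreme_separation_exact_p(self):
        # U = 0; brute force over C(4,2) rank assignments gives 2/6
        assert mann_whitney_u([1.0, 2.0], [3.0, 4.0]) == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        assert mann_whitney_u([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_symmetry(self):
        x, y = [1.0, 5.0, 3.0], [2.0, 8.0, 9.0, 4.0]
        assert mann_whitney_u(x, y) == pytest.approx(mann_whitney_u(y, x))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("nx,ny", [(2, 3), (3, 3), (4, 5), (5, 5)])
    def test_exact_path_matches_full_enumeration(self, nx, ny):
        """Exact two-sided p equals brute force over all rank assignments."""
        rng = np.random.default_rng(nx * 10 + ny)
        pooled = rng.permutation(np.arange(1.0, nx + ny + 1))  # tie-free ranks
        x, y = pooled[:nx], pooled[nx:]

        def u_stat(xs, ys):
            return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

        u_obs = u_stat(x, y)
        mu = nx * ny / 2
        count = 0
        total = 0
        for combo in itertools.combinations(range(nx + ny), nx):
            xs = pooled[list(combo)]
            ys = pooled[[i for i in range(nx + ny) if i not in combo]]
            total += 1
            if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
        assert mann_whitney_u(x, y) == pytest.approx(count / total, rel=1e-9)


def _bh_bruteforce(p):
    """Quadratic-time step-up: adj_i = min over j with p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = np.inf
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, m * p[i] / (pos + 1))
        adj[i] = min(running_min, 1.0)
    return adj


class TestBenjaminiHochberg:
    def test_step_up_oracle_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=1e-12, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_matches_bruteforce_and_bounds(self, pvals):
        adj = benjamini_hochberg(pvals)
        np.testing.assert_allclose(adj, _bh_bruteforce(pvals), rtol=1e-10)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_empty_and_invalid(self):
        assert len(benjamini_hochberg([])) == 0
        with pytest.raises(ValueError):
            benjamini_hochberg([0.0, 0.5])
        with pytest.raises(ValueError):
            benjamini_hochberg([1.5])


class TestTables:
    def _study(self, seed=0, effect=1.0):
        rng = np.random.default_rng(seed)
        n = 12
        base = rng.normal(15, 1, size=(n, 3))
        art = base + rng.normal(0, 0.1, size=(n, 3))
        art[:, 0] += effect
        ven = base + rng.normal(0, 0.1, size=(n, 3))
        E = pd.DataFrame(art - ven, columns=["m0", "m1", "m2"])
        log2 = pd.DataFrame(
            np.vstack([art, ven]),
            index=[f"s{i}A" for i in range(n)] + [f"s{i}V" for i in range(n)],
            columns=["m0", "m1", "m2"],
        )
        return E, log2, [f"s{i}A" for i in range(n)], [f"s{i}V" for i in range(n)]

    def test_vessel_table_shape_and_direction(self):
        E, log2, art, ven = self._study()
        tab = vessel_table(E, log2, art, ven, ["m0", "m1", "m2"])
        assert list(tab.columns[:4]) == [
            "metabolite", "fold_change", "p_unadjusted", "p_paired_t",
        ]
        top = tab.iloc[0]
        assert top["metabolite"] == "m0"
        assert top["fold_change"] > 1.5 and top["direction"] == "arterial"
        assert (tab["p_fdr"] >= tab["p_unadjusted"] - 1e-15).all()
        # sorted by |log2 FC| descending
        mags = np.abs(np.log2(tab["fold_change"]))
        assert (np.diff(mags) <= 1e-12).all()

    def test_trait_table_direction_is_explicit(self):
        rng = np.random.default_rng(1)
        vals = np.exp2(rng.normal(15, 0.2, size=(10, 2)))
        vals[:5, 0] *= 2.0
        df = pd.DataFrame(vals, index=[f"s{i}" for i in range(10)], columns=["m0", "m1"])
        labels = pd.Series(["g1"] * 5 + ["g2"] * 5, index=df.index)
        tab = trait_table(df, labels, "g1", "g2", ["m0", "m1"])
        assert tab.attrs["numerator"] == "g1"
        row = tab[tab["metabolite"] == "m0"].iloc[0]
        assert row["fold_change"] == pytest.approx(2.0, rel=0.2)
        assert row["direction"] == "g1"


class TestReplication:
    def _data(self, effect=2.0, seed=0, n=20):
        rng = np.random.default_rng(seed)
        vals = np.exp2(rng.normal(14, 0.5, size=(2 * n, 2)))
        vals[:n, 0] *= effect
        df = pd.DataFrame(
            vals, index=[f"s{i}" for i in range(2 * n)], columns=["m0", "m1"]
        )
        labels = pd.Series(["nulli"] * n + ["multi"] * n, index=df.index)
        return df, labels

    def test_strong_effect_replicates(self):
        df, labels = self._data()
        prior = pd.DataFrame(
            {"metabolite": ["m0"], "direction": ["up"]}
        )
        out = replication_test(df, labels, prior, "nulli", "multi")
        assert bool(out.iloc[0]["replicated"])

    def test_absent_metabolite_reported_not_measured(self):
        df, labels = self._data()
        prior = pd.DataFrame(
            {"metabolite": ["ghost", "m0"], "direction": ["up", "up"]}
        )
        out = replication_test(df, labels, prior, "nulli", "multi")
        rec = out[out["metabolite"] == "ghost"].iloc[0]
        assert rec["status"] == "not measured" and not rec["replicated"]

    def test_direction_mismatch_blocks_replication(self):
        df, labels = self._data()
        prior = pd.DataFrame({"metabolite": ["m0"], "direction": ["down"]})
        out = replication_test(df, labels, prior, "nulli", "multi")
        assert not bool(out.iloc[0]["replicated"])

    def test_null_feature_replication_rate_near_alpha(self):
        """A null metabolite replicates at ~ alpha/2 (two-sided p, one direction)."""
        hits = 0
        n_runs = 40
        for seed in range(n_runs):
            df, labels = self._data(effect=1.0, seed=seed)
            prior = pd.DataFrame({"metabolite": ["m1"], "direction": ["up"]})
            out = replication_test(df, labels, prior, "nulli", "multi")
            hits += bool(out.iloc[0]["replicated"])
        # direction agreement halves the two-sided alpha: expect ~2.5% +- binomial
        assert hits / n_runs <= 0.05 + 3 * np.sqrt(0.025 * 0.975 / n_runs)

    def test_empty_prior_raises(self):
        df, labels = self._data()
        with pytest.raises(ValueError):
            replication_test(df, labels, pd.DataFrame(columns=["metabolite", "direction"]),
                             "nulli", "multi")


class TestFoldChangeEstimatorFlags:
    def test_arithmetic_mean_of_ratios(self):
        E = _E([[1.0, -1.0]])  # ratios 2 and 0.5
        geo = paired_fold_change(E).iloc[0]
        ari = paired_fold_change(E, method="arithmetic").iloc[0]
        assert geo == pytest.approx(1.0)
        assert ari == pytest.approx(1.25)  # (2 + 0.5) / 2

    def test_ratio_of_means(self):
        df = pd.DataFrame({"f0": [1.0, 4.0, 2.0, 2.0]}, index=list("abcd"))
        labels = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        rom = group_fold_change(df, labels, "x", "y", method="ratio_of_means")
        assert rom.iloc[0] == pytest.approx(2.5 / 2.0)

    def test_unknown_method_rejected(self):
        E = _E([[1.0]])
        with pytest.raises(ValueError, match="method"):
            paired_fold_change(E, method="median")
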