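"""Preprocessing: tier merging, pH pair filter, imputation, batch alignment."""

import numpy as np
import pandas as pd
import pytest

from mlmetab import FeatureTable, merge_tiers, validate_pairs, impute, align_batches
from mlmetab.containers import ValidationError
from mlmetab.preprocess import AlignmentError, UnimputableError, clean_nonpositive

from conftest import make_pairs, make_table


def _tier_tables(n_mrm, n_tar, n_unt, n_samples=4, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n_samples)]
    tables = []
    for prefix, n, tier in (
        ("M", n_mrm, "mrm"),
        ("T", n_tar, "targeted"),
        ("U", n_unt, "untargeted"),
    ):
        vals = rng.uniform(10, 100, size=(n_samples, n))
        tables.append(
            make_table(
                vals,
                sample_ids=samples,
                feature_ids=[f"{prefix}{j}" for j in range(n)],
                tier=tier,
            )
        )
    return tables


class TestMergeTiers:
    def test_disjoint_tables_concatenate(self):
        m, t, u = _tier_tables(2, 3, 4)
        out = merge_tiers(m, t, u)
        assert out.n_features == 9

    def test_duplicate_kept_by_tier_priority(self):
        m, t, u = _tier_tables(2, 3, 4)
        out = merge_tiers(m, t, u, identity_map=[("U0", "M1")])
        assert "M1" in out.feature_ids and "U0" not in out.feature_ids
        out2 = merge_tiers(m, t, u, identity_map=[("T2", "U3")])
        assert "T2" in out2.feature_ids and "U3" not in out2.feature_ids

    def test_study_scale_counting_oracle(self):
        """30 MRM + 120 targeted + 280 untargeted with 3 + 11 links -> 416.

        Oracle: features minus one per cross-tier equivalence link (each
        link collapses exactly two features into one retained copy).
        """
        m, t, u = _tier_tables(30, 120, 280)
        links = [(f"T{j}", f"M{j}") for j in range(3)]
        links += [(f"U{j}", f"M{j + 5}") for j in range(5)]
        links += [(f"U{j + 5}", f"T{j + 50}") for j in range(6)]
        expected = 30 + 120 + 280 - len(links)
        out = merge_tiers(m, t, u, identity_map=links)
        assert out.n_features == expected == 416
        counts = out.tier_counts()
        assert counts["mrm"] == 30  # the highest tier never loses features
        assert counts["targeted"] == 120 - 3
        assert counts["untargeted"] == 280 - 11

    def test_sample_mismatch_raises(self):
        m, t, u = _tier_tables(2, 2, 2)
        t_bad = make_table(
            t.intensities.to_numpy()[:3],
            sample_ids=["s0", "s1", "sX"],
            feature_ids=list(t.feature_ids),
            tier="targeted",
        )
        with pytest.raises(AlignmentError):
            merge_tiers(m, t_bad, u)

    def test_contradictory_map_raises(self):
        m, t, u = _tier_tables(2, 2, 2)
        with pytest.raises(ValidationError):
            merge_tiers(m, t, u, identity_map=[("M0", "M1")])
        with pytest.raises(ValidationError):
            merge_tiers(m, t, u, identity_map=[("M0", "nope")])


class TestValidatePairs:
    def test_rule_keeps_strictly_lower_arterial_ph(self):
        pairs = make_pairs(1, ph_a=7.25, ph_v=7.33)
        res = validate_pairs(pairs)
        assert list(res.kept.subject_ids) == ["subj0"]
        assert res.removed == []

    def test_equal_ph_is_removed(self):
        pairs = make_pairs(1, ph_a=7.33, ph_v=7.33)
        res = validate_pairs(pairs)
        assert res.kept.n_subjects == 0
        assert res.removed == ["subj0"]

    def test_51_pairs_with_3_violators_keep_48(self):
        ph_a = [7.25] * 51
        ph_v = [7.33] * 51
        ph_a[4] = 7.40          # higher than venous
        ph_a[17] = ph_v[17]     # exact tie
        ph_a[33] = 7.50
        pairs = make_pairs(51, ph_a=ph_a, ph_v=ph_v)
        res = validate_pairs(pairs)
        assert res.kept.n_subjects == 48
        assert sorted(res.removed) == ["subj17", "subj33", "subj4"]

    def test_missing_ph_counted_separately(self):
        ph_a = [7.25, np.nan, 7.40]
        pairs = make_pairs(3, ph_a=ph_a, ph_v=[7.33] * 3)
        with pytest.warns(UserWarning, match="missing pH"):
            res = validate_pairs(pairs)
        assert res.excluded_missing_ph == ["subj1"]
        assert res.removed == ["subj2"]
        assert list(res.kept.subject_ids) == ["subj0"]

    def test_partition_is_exhaustive(self, noisy_study):
        _, pairs, _ = noisy_study
        res = validate_pairs(pairs)
        together = (
            set(res.kept.subject_ids) | set(res.removed) | set(res.excluded_missing_ph)
        )
        assert together == set(pairs.subject_ids)
        assert len(res.kept.subject_ids) + len(res.removed) + len(
            res.excluded_missing_ph
        ) == pairs.n_subjects


class TestImpute:
    def test_no_missing_returns_unchanged(self):
        table = make_table(np.array([[1.0, 2.0], [3.0, 4.0]]))
        out = impute(table)
        pd.testing.assert_frame_equal(out.intensities, table.intensities)

    def test_rank1_cell_recovered(self):
        """x_ij = r_i * c_j with one deletion: completion recovers the cell.

        Oracle: the rank-1 structure makes the deleted value r_i * c_j. On
        the log2 scale this is a one-component model (row effect plus
        column offset), so the completion is run at one component; a larger
        rank could represent the corrupted initialization exactly and make
        no progress.
        """
        r = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        c = np.array([2.0, 4.0, 8.0, 16.0, 32.0])
        vals = np.outer(r, c)
        expected = vals[2, 3]
        vals[2, 3] = np.nan
        out = impute(make_table(vals), n_components=1, tol=1e-12, max_iter=500)
        got = out.intensities.iloc[2, 3]
        assert abs(got - expected) / expected < 1e-6

    def test_observed_cells_bitwise_identical(self, noisy_study):
        table, _, _ = noisy_study
        table = clean_nonpositive(table)
        out = impute(table)
        mask = table.intensities.isna().to_numpy()
        before = table.intensities.to_numpy()[~mask]
        after = out.intensities.to_numpy()[~mask]
        assert np.array_equal(before, after)
        assert out.missing_fraction() == 0.0

    def test_deterministic_completion(self, noisy_study):
        table, _, _ = noisy_study
        a = impute(table).intensities
        b = impute(table).intensities
        pd.testing.assert_frame_equal(a, b)

    def test_fully_missing_feature_raises(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan], [3.0, np.nan]])
        with pytest.raises(UnimputableError, match="f1"):
            impute(make_table(vals))

    def test_excessive_missingness_raises(self):
        vals = np.ones((4, 4))
        holes = [(0, 0), (0, 1), (1, 1), (1, 2), (2, 2), (2, 3), (3, 3), (3, 0)]
        for i, j in holes:  # 50% missing, no row or column fully absent
            vals[i, j] = np.nan
        with pytest.raises(UnimputableError, match="missing fraction"):
            impute(make_table(vals))


class TestAlignBatches:
    def _two_batch_table(self, shift=1.5, n=6, p=4, seed=1):
        rng = np.random.default_rng(seed)
        log2_a = rng.normal(10, 1, size=(n, p))
        log2_b = log2_a + shift  # batch B = batch A + constant on log2 scale
        vals = np.exp2(np.vstack([log2_a, log2_b]))
        batch = pd.Series(
            ["A"] * n + ["B"] * n, index=[f"s{i}" for i in range(2 * n)]
        )
        return make_table(vals, sample_ids=list(batch.index), batch=batch)

    def test_single_batch_is_noop(self):
        table = make_table(np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]))
        out = align_batches(table)
        pd.testing.assert_frame_equal(out.intensities, table.intensities)

    def test_constant_offset_removed_exactly(self):
        table = self._two_batch_table()
        out = align_batches(table)
        log2 = out.log2()
        for fid in out.feature_ids:
            med_a = log2.loc[out.batch == "A", fid].median()
            med_b = log2.loc[out.batch == "B", fid].median()
            assert med_a == pytest.approx(med_b, abs=1e-10)

    def test_idempotent(self):
        table = self._two_batch_table(shift=0.7)
        once = align_batches(table)
        twice = align_batches(once)
        np.testing.assert_allclose(
            np.log2(twice.intensities), np.log2(once.intensities), atol=1e-10
        )

    def test_small_batch_left_unshifted(self):
        vals = np.exp2(np.arange(20, dtype=float).reshape(5, 4) / 4 + 8)
        batch = pd.Series(["A", "A", "A", "B", "B"], index=[f"s{i}" for i in range(5)])
        table = make_table(vals, sample_ids=list(batch.index), batch=batch)
        with pytest.warns(UserWarning, match="fewer than"):
            out = align_batches(table)
        pd.testing.assert_frame_equal(
            out.intensities.loc[["s3", "s4"]], table.intensities.loc[["s3", "s4"]]
        )

    def test_within_batch_order_preserved(self):
        table = self._two_batch_table(shift=2.0, seed=3)
        out = align_batches(table)
        for b in ("A", "B"):
            rows = table.batch[table.batch == b].index
            before = table.intensities.loc[rows].to_numpy()
            after = out.intensities.loc[rows].to_numpy()
            for j in range(before.shape[1]):
                assert np.array_equal(
                    np.argsort(before[:, j]), np.argsort(after[:, j])
                )


def test_clean_nonpositive_blanks_zero_and_negative():
    vals = np.array([[1.0, 0.0], [-2.0, 3.0]])
    df = pd.DataFrame(vals, index=["s0", "s1"], columns=["f0", "f1"])
    table = FeatureTable(
        df.mask(df <= 0),  # container itself rejects non-positive values
        pd.Series("mrm", index=df.columns),
        pd.Series("B1", index=df.index),
    )
    assert table.missing_fraction() == 0.5
    cleaned = clean_nonpositive(table)
    assert cleaned.missing_fraction() == 0.5
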