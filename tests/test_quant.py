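"""Quantitative preprocessing and SAM differential testing."""

import numpy as np
import pandas as pd
import pytest

from phosmap.quant import (
    QuantMatrix,
    filter_missing,
    impute_knn,
    normalize_log2,
    sam_differential,
)


def _qm(values, groups=None, log2=False, sites=None, samples=None):
    arr = np.asarray(values, dtype=float)
    sites = sites or [f"p{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    g = None
    if groups is not None:
        g = pd.Series(groups, index=samples)
    return QuantMatrix(
        values=pd.DataFrame(arr, index=sites, columns=samples),
        groups=g,
        log2_transformed=log2,
    )


class TestNormalizeLog2:
    def test_median_division_then_log2(self):
        qm = _qm([[2.0], [8.0], [5.0]])
        out = normalize_log2(qm)
        col = out.values.iloc[:, 0]
        assert col["p0"] == pytest.approx(np.log2(2 / 5))
        assert col["p1"] == pytest.approx(np.log2(8 / 5))
        assert col["p2"] == pytest.approx(0.0)

    def test_constant_sample_becomes_zero(self):
        out = normalize_log2(_qm([[4.0], [4.0], [4.0]]))
        assert (out.values == 0).all().all()

    def test_post_transform_medians_are_zero(self):
        rng = np.random.default_rng(0)
        qm = _qm(rng.lognormal(3, 1, (21, 5)))
        out = normalize_log2(qm)
        assert np.allclose(out.values.median(axis=0), 0.0, atol=1e-12)

    def test_missing_entries_stay_missing(self):
        qm = _qm([[2.0, np.nan], [8.0, 3.0], [5.0, 6.0]])
        out = normalize_log2(qm)
        assert np.isnan(out.values.iloc[0, 1])

    def test_nonpositive_value_named(self):
        with pytest.raises(ValueError, match="p1.*s0"):
            _qm([[2.0], [-1.0]])

    def test_all_missing_sample_rejected(self):
        qm = _qm([[2.0, np.nan], [8.0, np.nan]])
        with pytest.raises(ValueError, match="s1"):
            normalize_log2(qm)


class TestFilterMissing:
    def test_over_half_missing_removed(self):
        vals = [[1, np.nan, np.nan, np.nan, 2], [1, 2, 3, 4, 5]]
        out, report = filter_missing(_qm(vals), 0.5)
        assert list(out.values.index) == ["p1"]
        assert report.iloc[0]["missing_fraction"] == pytest.approx(0.6)

    def test_exactly_at_threshold_kept(self):
        vals = [[1, np.nan, 2, np.nan]]  # 0.5 missing
        out, _ = filter_missing(_qm(vals), 0.5)
        assert len(out.values) == 1

    def test_threshold_zero_keeps_only_complete(self):
        vals = [[1, 2], [np.nan, 2]]
        out, _ = filter_missing(_qm(vals), 0.0)
        assert list(out.values.index) == ["p0"]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(3, 1, (50, 8))
        vals[rng.random((50, 8)) < 0.3] = np.nan
        qm = _qm(vals)
        kept = [
            set(filter_missing(qm, t)[0].values.index)
            for t in (0.0, 0.2, 0.4, 0.6, 1.0)
        ]
        for smaller, larger in zip(kept, kept[1:]):
            assert smaller <= larger


def knn_impute_oracle(values, k):
    """Exhaustive-search reference for the kNN imputation contract."""
    X = values.copy()
    n, _ = X.shape
    out = X.copy()
    for i in range(n):
        for s in range(X.shape[1]):
            if not np.isnan(X[i, s]):
                continue
            cands = []
            for j in range(n):
                if j == i or np.isnan(X[j, s]):
                    continue
                shared = [
                    t
                    for t in range(X.shape[1])
                    if not np.isnan(X[i, t]) and not np.isnan(X[j, t])
                ]
                if not shared:
                    continue
                d = np.sqrt(
                    sum((X[i, t] - X[j, t]) ** 2 for t in shared) / len(shared)
                )
                cands.append((d, j))
            if not cands:
                out[i, s] = np.nanmean(X[i])
                continue
            cands.sort()
            chosen = [j for _, j in cands[:k]]
            out[i, s] = np.mean([X[j, s] for j in chosen])
    return out


class TestImputeKnn:
    def test_identical_neighbour_copies_value(self):
        vals = [[1.0, 2.0, 3.0], [1.0, 2.0, np.nan]]
        out = impute_knn(_qm(vals, log2=True), k=1)
        assert out.values.iloc[1, 2] == pytest.approx(3.0)

    def test_matches_exhaustive_reference_on_seeded_matrices(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            vals = rng.normal(20, 2, (20, 6))
            mask = rng.random((20, 6)) < 0.1
            # keep >= 2 present per row
            for i in range(20):
                while mask[i].sum() > 4:
                    mask[i, rng.integers(6)] = False
            vals[mask] = np.nan
            qm = _qm(vals, log2=True)
            got = impute_knn(qm, k=10).values.to_numpy()
            want = knn_impute_oracle(vals, k=10)
            assert np.allclose(got, want)

    def test_observed_cells_untouched(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, (15, 6))
        vals[rng.random((15, 6)) < 0.15] = np.nan
        vals[:, 0] = rng.normal(0, 1, 15)  # ensure >= 2 present
        vals[:, 1] = rng.normal(0, 1, 15)
        qm = _qm(vals, log2=True)
        out = impute_knn(qm, k=3)
        obs = ~np.isnan(vals)
        assert np.array_equal(out.values.to_numpy()[obs], vals[obs])
        assert not np.isnan(out.values.to_numpy()).any()

    def test_k_larger_than_neighbour_pool_warns_and_clamps(self, caplog):
        vals = [[1.0, 2.0, np.nan], [1.1, 2.1, 3.0], [5.0, 6.0, 7.0]]
        out = impute_knn(_qm(vals, log2=True), k=10)
        assert out.values.iloc[0, 2] == pytest.approx(np.mean([3.0, 7.0]))
        assert any("fewer than k" in r.message for r in caplog.records)

    def test_sparse_site_rejected(self):
        vals = [[1.0, np.nan, np.nan], [1.0, 2.0, 3.0]]
        with pytest.raises(ValueError, match="filter_missing"):
            impute_knn(_qm(vals, log2=True))


class TestSamDifferential:
    def _simulate(self, seed, n_null=200, n_diff=20, delta=3.0, sd=0.3, n1=4, n2=4):
        rng = np.random.default_rng(seed)
        base = rng.normal(20, 2, n_null + n_diff)
        X = base[:, None] + rng.normal(0, sd, (n_null + n_diff, n1 + n2))
        X[n_null:, n1:] += delta
        groups = ["A"] * n1 + ["B"] * n2
        return _qm(X, groups=groups, log2=True), n_null

    def test_planted_sites_recovered_null_sites_quiet(self):
        qm, n_null = self._simulate(0)
        table = sam_differential(qm, n_perm=200, seed=1)
        planted = table.iloc[n_null:]
        nulls = table.iloc[:n_null]
        assert planted.significant.mean() >= 0.9
        assert nulls.significant.sum() == 0
        # no call below the fold-change gate
        assert (table[table.significant].log2_fc.abs() >= 1.0).all()

    def test_label_flip_negates_statistics_preserves_calls(self):
        qm, _ = self._simulate(3)
        flipped = QuantMatrix(
            values=qm.values,
            groups=qm.groups.map({"A": "B", "B": "A"}),
            log2_transformed=True,
        )
        t1 = sam_differential(qm, n_perm=200, seed=5)
        t2 = sam_differential(flipped, n_perm=200, seed=5)
        assert np.allclose(t1.log2_fc, -t2.log2_fc)
        assert np.allclose(t1.d_statistic, -t2.d_statistic)
        assert (t1.significant == t2.significant).all()

    def test_degenerate_identical_groups_call_nothing(self):
        vals = np.tile(np.arange(10.0)[:, None], (1, 8))
        qm = _qm(vals, groups=["A"] * 4 + ["B"] * 4, log2=True)
        table = sam_differential(qm, n_perm=100, seed=0)
        assert table.significant.sum() == 0

    def test_pure_null_fdr_controlled(self):
        false_calls = 0
        total_calls = 0
        for seed in range(25):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(20, 0.3, (300, 8)) + rng.normal(0, 2, (300, 1))
            qm = _qm(X, groups=["A"] * 4 + ["B"] * 4, log2=True)
            table = sam_differential(qm, n_perm=200, fdr_threshold=0.01, seed=seed)
            total_calls += len(table)
            false_calls += int(table.significant.sum())
        # nominal FDR 0.01: essentially no null calls expected
        assert false_calls <= max(2, 0.001 * total_calls)

    def test_determinism_under_seed(self):
        qm, _ = self._simulate(7)
        t1 = sam_differential(qm, n_perm=50, seed=9)
        t2 = sam_differential(qm, n_perm=50, seed=9)
        assert t1.equals(t2)

    def test_bad_inputs_rejected(self):
        qm, _ = self._simulate(0)
        with pytest.raises(ValueError):
            sam_differential(QuantMatrix(qm.values, None, True))
        one_sample = QuantMatrix(
            qm.values.iloc[:, :3],
            pd.Series(["A", "A", "B"], index=qm.values.columns[:3]),
            True,
        )
        with pytest.raises(ValueError):
            sam_differential(one_sample)
        three_groups = QuantMatrix(
            qm.values,
            pd.Series(["A", "A", "B", "B", "C", "C", "C", "C"], index=qm.values.columns),
            True,
        )
        with pytest.raises(ValueError):
            sam_differential(three_groups)
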