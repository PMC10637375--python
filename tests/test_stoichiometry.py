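"""Subunit correlation, UPGMA clustering and segregation analysis."""

import numpy as np
import pandas as pd
import pytest

from gabafc import (
    cluster_correlation,
    robust_standardize,
    segregation_cluster,
    subunit_correlation,
)
from gabafc.errors import EstimationError, PreconditionError
from gabafc.stoichiometry import CorrelationResult


def frame(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols)


class TestCorrelation:
    def test_duplicated_column_correlates_perfectly(self):
        df = frame({"a": [1, 2, 3, 5], "b": [1, 2, 3, 5], "c": [4, 1, 2, 2]})
        c = subunit_correlation(df)
        assert c.r.loc["a", "b"] == pytest.approx(1.0)
        assert c.p.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_negated_column_gives_minus_one(self):
        df = frame({"a": [1, 2, 3], "b": [6, 4, 2], "c": [0, 5, 1]})
        c = subunit_correlation(df)
        assert c.r.loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_variance_column_is_nan(self):
        df = frame({"a": [1, 2, 3], "b": [7, 7, 7], "c": [2, 0, 1]})
        c = subunit_correlation(df)
        assert np.isnan(c.r.loc["a", "b"])
        assert np.isnan(c.p.loc["b", "b"])

    def test_too_few_rows_refused(self):
        with pytest.raises(EstimationError):
            subunit_correlation(frame({"a": [1, 2], "b": [3, 4]}))

    def test_matches_two_loop_oracle(self, rng, panel):
        df = pd.DataFrame(
            rng.uniform(0, 10, size=(8, 19)), columns=panel.genes
        )
        c = subunit_correlation(df)
        X = df.to_numpy()
        n = 8
        for i in range(19):
            for j in range(19):
                xi, xj = X[:, i], X[:, j]
                cov = ((xi - xi.mean()) * (xj - xj.mean())).sum()
                denom = np.sqrt(((xi - xi.mean()) ** 2).sum()) * np.sqrt(
                    ((xj - xj.mean()) ** 2).sum()
                )
                assert c.r.iloc[i, j] == pytest.approx(cov / denom, abs=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        scaled = df.copy()
        scaled["a"] = 3.5 * df["a"] + 7.0
        a = subunit_correlation(df).r
        b = subunit_correlation(scaled).r
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_p_decreases_with_abs_r_at_fixed_n(self):
        n = 10
        rng = np.random.default_rng(5)
        base = rng.normal(size=n)
        noise = rng.normal(size=n)
        ps, rs = [], []
        for w in (0.2, 1.0, 5.0):
            df = frame({"a": base, "b": w * base + noise, "c": rng.normal(size=n)})
            c = subunit_correlation(df)
            rs.append(abs(c.r.loc["a", "b"]))
            ps.append(c.p.loc["a", "b"])
        assert rs == sorted(rs)
        assert ps == sorted(ps, reverse=True)


def brute_force_upgma(d: np.ndarray):
    """Independent UPGMA: merge the closest pair, average distances
    weighted by cluster sizes; returns merge heights sorted."""
    n = d.shape[0]
    active = {i: [i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    next_id = n
    while len(active) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        members = active[a] + active[b]
        for k in list(active):
            if k in (a, b):
                continue
            da = dist[tuple(sorted((a, k)))]
            db = dist[tuple(sorted((b, k)))]
            na, nb = len(active[a]), len(active[b])
            dist[tuple(sorted((next_id, k)))] = (na * da + nb * db) / (na + nb)
        for key in [k for k in dist if a in k or b in k]:
            del dist[key]
        del active[a], active[b]
        active[next_id] = members
        next_id += 1
    return sorted(heights)


class TestClusterCorrelation:
    def _corr(self, r: np.ndarray, names):
        r = np.asarray(r, dtype=float)
        p = np.full_like(r, 0.5)
        return CorrelationResult(
            r=pd.DataFrame(r, index=names, columns=names),
            p=pd.DataFrame(p, index=names, columns=names),
            n_obs=8, mode="dataset_means",
        )

    def test_perfectly_correlated_pair_merges_first_at_zero(self):
        r = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        res = cluster_correlation(self._corr(r, list("abc")))
        first = res.linkage[0]
        assert sorted(first[:2].astype(int).tolist()) == [0, 1]
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_equal_correlations_give_equal_heights(self):
        r = np.full((3, 3), 0.3)
        np.fill_diagonal(r, 1.0)
        res = cluster_correlation(self._corr(r, list("abc")))
        np.testing.assert_allclose(res.linkage[:, 2], 0.7, atol=1e-12)

    def test_merge_heights_match_brute_force_upgma(self, rng):
        X = rng.normal(size=(12, 10))
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(10)])
        c = subunit_correlation(df)
        res = cluster_correlation(c)
        d = 1 - c.r.to_numpy()
        np.fill_diagonal(d, 0)
        expected = brute_force_upgma(d)
        np.testing.assert_allclose(
            sorted(res.linkage[:, 2].tolist()), expected, atol=1e-12
        )

    def test_nan_columns_excluded_and_listed(self):
        r = np.array(
            [[1, 0.5, np.nan], [0.5, 1, np.nan], [np.nan, np.nan, np.nan]]
        )
        res = cluster_correlation(self._corr(r, list("abc")))
        assert res.excluded == ["c"]
        assert res.items == ["a", "b"]

    def test_fewer_than_two_usable_refused(self):
        r = np.full((3, 3), np.nan)
        with pytest.raises(EstimationError):
            cluster_correlation(self._corr(r, list("abc")))


class TestRobustStandardize:
    def test_closed_form_column(self):
        df = frame({"a": [0.0, 10.0, 20.0], "b": [1.0, 2.0, 4.0]})
        out, flagged = robust_standardize(df)
        expected = 10 / (1.4826 * 10)  # = 0.67448975...
        np.testing.assert_allclose(
            out["a"], [-expected, 0.0, expected], atol=1e-9
        )
        assert flagged == []

    def test_constant_column_zeroed_and_flagged(self):
        df = frame({"a": [5.0, 5.0, 5.0], "b": [1.0, 2.0, 3.0]})
        out, flagged = robust_standardize(df)
        assert flagged == ["a"]
        assert (out["a"] == 0).all()

    def test_standardized_median_is_zero(self, rng):
        df = pd.DataFrame(rng.uniform(0, 100, size=(9, 5)))
        out, _ = robust_standardize(df)
        np.testing.assert_allclose(out.median(axis=0), 0.0, atol=1e-12)

    def test_single_row_refused(self):
        with pytest.raises(PreconditionError):
            robust_standardize(frame({"a": [1.0]}))


class TestSegregation:
    def _planted_table(self, rng, panel):
        from tests.conftest import contrast_proportions

        opc_p, neuron_p = contrast_proportions()
        opc_center = 100 * np.asarray(opc_p)      # alpha3/beta1/gamma3 heavy
        neuron_center = 100 * np.asarray(neuron_p)  # alpha1/beta2/gamma2 heavy
        rows, types = [], []
        for i in range(5):
            rows.append(opc_center + rng.normal(0, 0.1, 19))
            types.append("OPC")
        for i in range(5):
            rows.append(neuron_center + rng.normal(0, 0.1, 19))
            types.append("neuron")
        table = pd.DataFrame(
            rows, columns=panel.genes,
            index=[f"ds{i}_{t}" for i, t in enumerate(types)],
        )
        return table, pd.Series(types, index=table.index)

    def test_planted_profiles_recovered_with_perfect_ari(self, rng, panel):
        table, types = self._planted_table(rng, panel)
        res = segregation_cluster(table, types, k=2)
        assert res.ari == pytest.approx(1.0)

    def test_identical_rows_give_near_zero_ari(self, panel):
        table = pd.DataFrame(
            np.ones((6, 19)), columns=panel.genes,
            index=[f"r{i}" for i in range(6)],
        )
        types = pd.Series(["OPC"] * 3 + ["neuron"] * 3, index=table.index)
        res = segregation_cluster(table, types, k=2)
        assert abs(res.ari) < 0.5  # no structure to recover

    def test_single_cell_type_gives_nan_ari(self, rng, panel):
        table, _ = self._planted_table(rng, panel)
        types = pd.Series(["OPC"] * 10, index=table.index)
        res = segregation_cluster(table, types, k=2)
        assert np.isnan(res.ari)
        assert res.row_cluster.linkage.shape == (9, 4)

    def test_row_permutation_preserves_heights_and_ari(self, rng, panel):
        table, types = self._planted_table(rng, panel)
        perm = rng.permutation(len(table))
        table_p = table.iloc[perm]
        types_p = types.iloc[perm]
        a = segregation_cluster(table, types, k=2)
        b = segregation_cluster(table_p, types_p, k=2)
        np.testing.assert_allclose(
            sorted(a.row_cluster.linkage[:, 2]),
            sorted(b.row_cluster.linkage[:, 2]),
            atol=1e-9,
        )
        assert a.ari == pytest.approx(b.ari)
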