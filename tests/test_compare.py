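"""Normality routing, two-group tests, fold change and stars."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import qpcrdiff as q
from qpcrdiff.compare import MANN_WHITNEY, STUDENT_T, ks_normality, mann_whitney_p


def _norm_from(values: dict[str, np.ndarray], gene="G") -> q.NormalizedTable:
    frames, labels = [], []
    for grp, vals in values.items():
        frames.append(pd.Series(vals))
        labels += [grp] * len(vals)
    data = pd.concat(frames, ignore_index=True).to_frame(gene)
    data.index = [f"s{i}" for i in range(len(data))]
    return q.NormalizedTable(
        neg_delta_ct=data, group=pd.Series(labels, index=data.index)
    )


class TestKsNormality:
    def test_exact_normal_quantiles_pass(self):
        """Points at the (i-0.5)/n normal quantiles minimize the KS
        distance; check against a brute-force D on the sorted sample."""
        n = 50
        x = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        p = ks_normality(x)
        assert p > 0.5
        # brute-force D against the same plug-in normal law
        mu, sd = x.mean(), x.std(ddof=1)
        cdf = stats.norm.cdf(np.sort(x), mu, sd)
        d_brute = max(
            np.max(np.arange(1, n + 1) / n - cdf),
            np.max(cdf - np.arange(0, n) / n),
        )
        d_scipy = stats.kstest(x, "norm", args=(mu, sd)).statistic
        assert d_brute == pytest.approx(d_scipy, abs=1e-12)

    def test_skewed_sample_fails(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(100) ** 2
        assert ks_normality(x) < 0.05

    def test_short_group_gives_missing_with_warning(self):
        norm = _norm_from({"a": np.array([1.0, 2.0]), "b": np.arange(5.0)})
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = q.normality_by_group(norm, "G")
        assert np.isnan(out["a"]) and not np.isnan(out["b"])

    def test_unknown_gene_or_group_rejected(self, tiny_norm):
        with pytest.raises(KeyError):
            q.normality_by_group(tiny_norm, "NOPE")
        with pytest.raises(KeyError):
            q.normality_by_group(tiny_norm, "G", ["zzz"])


class TestRouteTest:
    def test_any_failing_group_routes_nonparametric(self):
        p = pd.Series({"g1": 0.3, "g2": 0.004, "g3": 0.001, "g4": 0.002})
        assert q.route_test(p) == MANN_WHITNEY

    def test_all_passing_routes_parametric(self):
        p = pd.Series({"g1": 0.3, "g2": 0.8})
        assert q.route_test(p) == STUDENT_T

    def test_override_honored(self):
        p = pd.Series({"g1": 0.001})
        assert q.route_test(p, override=STUDENT_T) == STUDENT_T

    def test_no_finite_p_rejected(self):
        with pytest.raises(ValueError):
            q.route_test(pd.Series({"g1": np.nan}))


class TestCompareGroups:
    def test_mann_whitney_exact_small_sample(self):
        norm = _norm_from({"a": np.array([1.0, 2, 3]), "b": np.array([4.0, 5, 6])})
        rec = q.compare_groups(norm, "G", "a", "b", MANN_WHITNEY)
        assert rec.p_value == pytest.approx(0.1)
        assert rec.n_a == rec.n_b == 3

    def test_identical_groups_unit_fc_and_p(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        norm = _norm_from({"a": vals, "b": vals})
        rec = q.compare_groups(norm, "G", "a", "b", MANN_WHITNEY)
        assert rec.fold_change == pytest.approx(1.0)
        assert rec.p_value == pytest.approx(1.0)

    def test_fc_from_median_difference(self):
        norm = _norm_from(
            {"a": np.array([-3.0, -3, -3]), "b": np.array([-4.0, -4, -4])}
        )
        rec = q.compare_groups(norm, "G", "a", "b", STUDENT_T)
        assert rec.fold_change == pytest.approx(2.0)

    def test_fc_antisymmetry_p_preserved(self, tiny_norm):
        ab = q.compare_groups(tiny_norm, "G", "a", "b", MANN_WHITNEY)
        ba = q.compare_groups(tiny_norm, "G", "b", "a", MANN_WHITNEY)
        assert ab.fold_change * ba.fold_change == pytest.approx(1.0)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_same_group_rejected(self, tiny_norm):
        with pytest.raises(ValueError):
            q.compare_groups(tiny_norm, "G", "a", "a", MANN_WHITNEY)

    def test_insufficient_data_names_group(self):
        norm = _norm_from({"a": np.array([1.0]), "b": np.arange(4.0)})
        with pytest.raises(ValueError, match="'a'"):
            q.compare_groups(norm, "G", "a", "b", MANN_WHITNEY)

    def test_exact_mw_matches_enumeration(self):
        """Exact two-sided Mann–Whitney p equals the exhaustive
        permutation tail probability (tie-free pooled samples)."""
        rng = np.random.default_rng(3)
        for n_a in (2, 3, 4):
            for n_b in (2, 3):
                pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))
                a, b = pooled[:n_a], pooled[n_a:]
                p = mann_whitney_p(a, b)
                assert p == pytest.approx(_mw_enumeration(a, b), abs=1e-12)


def _mw_enumeration(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact MW p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    n_a, n = len(a), len(pooled)
    max_u = n_a * (n - n_a)

    def u_stat(idx_a: tuple) -> float:
        x = pooled[list(idx_a)]
        y = np.delete(pooled, list(idx_a))
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)

    u_obs = min(u_stat(tuple(range(n_a))), max_u - u_stat(tuple(range(n_a))))
    hits = total = 0
    for idx in combinations(range(n), n_a):
        u = u_stat(idx)
        hits += min(u, max_u - u) <= u_obs + 1e-9
        total += 1
    return hits / total


class TestPairwiseTable:
    def test_six_records_for_four_groups(self, example_norm):
        out = q.pairwise_table(example_norm, "AKT1", "Group1")
        assert len(out) == 6

    def test_reference_listed_second(self, example_norm):
        out = q.pairwise_table(example_norm, "AKT1", "Group1")
        with_ref = out[(out["group_a"] == "Group1") | (out["group_b"] == "Group1")]
        assert (with_ref["group_b"] == "Group1").all()

    def test_two_groups_one_record(self, tiny_norm):
        out = q.pairwise_table(tiny_norm, "G", "a")
        assert len(out) == 1

    def test_reference_must_be_selected(self, tiny_norm):
        with pytest.raises(ValueError):
            q.pairwise_table(tiny_norm, "G", "zzz")

    def test_akt1_worked_example(self, example_norm):
        """AKT1: skewed groups route nonparametric; Group3 strongly and
        Group4 moderately above the reference group."""
        normality = q.normality_by_group(example_norm, "AKT1")
        assert (normality < 0.05).sum() >= 3
        out = q.pairwise_table(example_norm, "AKT1", "Group1")
        assert (out["test_name"] == MANN_WHITNEY).all()
        row3 = out[(out["group_a"] == "Group3") & (out["group_b"] == "Group1")]
        row4 = out[(out["group_a"] == "Group4") & (out["group_b"] == "Group1")]
        assert float(row3["p_value"].iloc[0]) < 0.001
        assert float(row4["p_value"].iloc[0]) < 0.05


class TestStars:
    @pytest.mark.parametrize(
        "p,label",
        [
            (0.03, "*"),
            (0.05, "ns"),
            (0.2, "ns"),
            (0.01, "**"),
            (0.001, "***"),
            (0.0001, "****"),
            (0.0, "****"),
        ],
    )
    def test_scheme(self, p, label):
        assert q.stars(p) == label

    def test_missing_p_gives_missing_label(self):
        assert q.stars(float("nan")) is None
        assert q.stars(None) is None

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            q.stars(1.5)
        with pytest.raises(ValueError):
            q.stars(-0.1)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_monotone(self, p1, p2):
        order = ["****", "***", "**", "*", "ns"]
        lo, hi = sorted((p1, p2))
        assert order.index(q.stars(lo)) <= order.index(q.stars(hi))
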