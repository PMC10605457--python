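"""Per-group correlation matrices, gating, dR-val and scatter stats."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import qpcrdiff as q
from qpcrdiff.diffcorr import PEARSON, SPEARMAN, spearman_with_p


def _norm(df: pd.DataFrame, labels: list[str]) -> q.NormalizedTable:
    df = df.copy()
    df.index = [f"s{i}" for i in range(len(df))]
    return q.NormalizedTable(
        neg_delta_ct=df, group=pd.Series(labels, index=df.index)
    )


class TestDrVal:
    def test_worked_example(self):
        assert round(q.dr_val(0.43, -0.48), 2) == 0.91

    def test_equal_inputs_zero(self):
        assert q.dr_val(0.7, 0.7) == 0.0

    def test_full_flip_is_two(self):
        assert q.dr_val(1.0, -1.0) == 2.0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b = rng.uniform(-1, 1, 2)
            assert q.dr_val(a, b) == q.dr_val(b, a)
            assert 0.0 <= q.dr_val(a, b) <= 2.0


class TestChooseMethod:
    def test_override(self, tiny_norm):
        assert q.choose_corr_method(tiny_norm, override=PEARSON) == PEARSON

    def test_skewed_gene_forces_spearman(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"A": rng.standard_normal(60), "B": rng.standard_normal(60) ** 2}
        )
        norm = _norm(df, ["g"] * 60)
        assert q.choose_corr_method(norm) == SPEARMAN

    def test_all_normal_gives_pearson(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"A": rng.standard_normal(60), "B": rng.standard_normal(60)}
        )
        norm = _norm(df, ["g"] * 60)
        assert q.choose_corr_method(norm) == PEARSON

    def test_unknown_override_rejected(self, tiny_norm):
        with pytest.raises(ValueError):
            q.choose_corr_method(tiny_norm, override="kendall")


class TestCorrelationMatrix:
    def test_monotone_pair_spearman_one(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"A": x, "B": np.exp(x)})
        gc = q.correlation_matrix(_norm(df, ["g"] * 10), "g", SPEARMAN)
        assert gc.r.loc["A", "B"] == pytest.approx(1.0)
        assert gc.r_gated.loc["A", "B"] == pytest.approx(1.0)

    def test_nonsignificant_coefficient_zeroed(self):
        # 4 tie-free points with |rho| = 0.4: exact permutation p = 0.75
        df = pd.DataFrame({"A": [1.0, 2, 3, 4], "B": [2.0, 1, 4, 3]})
        gc = q.correlation_matrix(_norm(df, ["g"] * 4), "g", SPEARMAN, alpha=0.05)
        assert abs(gc.r.loc["A", "B"]) > 0
        assert gc.p.loc["A", "B"] > 0.05
        assert gc.r_gated.loc["A", "B"] == 0.0

    def test_symmetry_unit_diagonal(self, example_norm):
        gc = q.correlation_matrix(example_norm, "Group1", SPEARMAN)
        r = gc.r.to_numpy()
        assert np.allclose(r, r.T, equal_nan=True)
        assert np.allclose(np.diag(r), 1.0)
        assert (gc.n.to_numpy() <= (example_norm.group == "Group1").sum()).all()

    def test_sparse_pair_left_missing(self):
        df = pd.DataFrame(
            {"A": [1.0, 2, 3, 4, 5], "B": [np.nan, np.nan, np.nan, 4.0, 5.0]}
        )
        gc = q.correlation_matrix(_norm(df, ["g"] * 5), "g", SPEARMAN)
        assert np.isnan(gc.r.loc["A", "B"])
        assert np.isnan(gc.r_gated.loc["A", "B"])
        assert gc.n.loc["A", "B"] == 2

    def test_raising_alpha_never_loses_nonzero_entries(self, example_norm):
        sub = q.NormalizedTable(
            neg_delta_ct=example_norm.neg_delta_ct.iloc[:, :12],
            group=example_norm.group,
        )
        counts = []
        for alpha in (0.001, 0.01, 0.05, 0.2, 1.0):
            gc = q.correlation_matrix(sub, "Group1", SPEARMAN, alpha=alpha)
            counts.append(int((gc.r_gated.to_numpy() != 0).sum()))
        assert counts == sorted(counts)

    def test_unknown_group_rejected(self, tiny_norm):
        with pytest.raises(KeyError):
            q.correlation_matrix(tiny_norm, "zzz")

    def test_tiny_group_rejected(self):
        df = pd.DataFrame({"A": [1.0, 2], "B": [2.0, 1]})
        with pytest.raises(ValueError, match="fewer than 3"):
            q.correlation_matrix(_norm(df, ["g"] * 2), "g")


class TestSpearmanExact:
    def test_matches_permutation_oracle(self):
        """Exact Spearman p equals exhaustive permutation of the data
        for n ≤ 6 (tie-free)."""
        rng = np.random.default_rng(5)
        for n in (4, 5, 6):
            x = rng.permutation(np.arange(1.0, n + 1))
            y = rng.normal(size=n)
            rho, p = spearman_with_p(x, y)
            null = [
                stats.spearmanr(x, np.array(perm)).statistic
                for perm in permutations(y)
            ]
            p_oracle = np.mean([abs(r) >= abs(rho) - 1e-12 for r in null])
            assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=50), rng.normal(size=50)
        rho, p = spearman_with_p(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestDrvalTable:
    def _correlations(self, norm, groups, alpha=0.05):
        return {
            g: q.correlation_matrix(norm, g, SPEARMAN, alpha) for g in groups
        }

    def test_identical_groups_give_zero(self):
        rng = np.random.default_rng(3)
        block = rng.normal(size=(20, 3))
        df = pd.DataFrame(
            np.vstack([block, block]), columns=["A", "B", "C"]
        )
        norm = _norm(df, ["g1"] * 20 + ["g2"] * 20)
        table = q.drval_table(self._correlations(norm, ["g1", "g2"]), "g1")
        assert np.allclose(table["dr_val"].dropna(), 0.0)

    def test_reference_restriction_and_all_pairs(self, example_norm):
        sub = q.NormalizedTable(
            neg_delta_ct=example_norm.neg_delta_ct.iloc[:, :8],
            group=example_norm.group,
        )
        corrs = self._correlations(sub, sub.group_levels)
        ref_only = q.drval_table(corrs, "Group1")
        full = q.drval_table(corrs, "Group1", all_pairs=True)
        n_gene_pairs = 8 * 7 // 2
        assert len(ref_only) == 3 * n_gene_pairs  # n−1 group pairs
        assert len(full) == 6 * n_gene_pairs  # n(n−1)/2 group pairs
        assert set(ref_only["group_a"]) == {"Group1"}

    def test_sorted_descending_within_bounds(self, example_norm):
        sub = q.NormalizedTable(
            neg_delta_ct=example_norm.neg_delta_ct.iloc[:, :8],
            group=example_norm.group,
        )
        table = q.drval_table(self._correlations(sub, sub.group_levels), "Group1")
        vals = table["dr_val"].dropna().to_numpy()
        assert (np.diff(vals) <= 1e-12).all()
        assert ((vals >= 0) & (vals <= 2)).all()

    def test_planted_flip_ranks_first(self, example_norm):
        table = q.drval_table(
            self._correlations(example_norm, ["Group1", "Group3"]), "Group1"
        )
        top = table.iloc[0]
        assert {top["gene_i"], top["gene_j"]} == {"PCNA", "KDM5B"}
        assert top["dr_val"] == pytest.approx(0.91, abs=0.2)

    def test_mismatched_runs_rejected(self, example_norm):
        corrs = {
            "Group1": q.correlation_matrix(example_norm, "Group1", SPEARMAN, 0.05),
            "Group2": q.correlation_matrix(example_norm, "Group2", SPEARMAN, 0.01),
        }
        with pytest.raises(ValueError, match="share"):
            q.drval_table(corrs, "Group1")

    def test_missing_reference_rejected(self, tiny_norm):
        corrs = {}
        with pytest.raises(KeyError):
            q.drval_table(corrs, "a")


class TestPairScatterStats:
    def test_worked_example_pair(self, example_norm):
        out = q.pair_scatter_stats(
            example_norm, "PCNA", "KDM5B", ["Group1", "Group3"], SPEARMAN
        ).set_index("group")
        assert out.loc["Group1", "r"] == pytest.approx(0.43, abs=0.15)
        assert out.loc["Group3", "r"] == pytest.approx(-0.48, abs=0.15)
        assert out.loc["Group1", "r"] > 0 > out.loc["Group3", "r"]

    def test_self_pair_r_one(self, example_norm):
        out = q.pair_scatter_stats(
            example_norm, "TP53", "TP53", ["Group1"], SPEARMAN
        )
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_perfect_negative_linear(self):
        x = np.arange(8.0)
        df = pd.DataFrame({"A": x, "B": -2 * x + 1})
        out = q.pair_scatter_stats(
            _norm(df, ["g"] * 8), "A", "B", ["g"], PEARSON
        )
        assert out["r"].iloc[0] == pytest.approx(-1.0)
        assert out["slope"].iloc[0] == pytest.approx(-2.0)

    def test_too_few_points_names_group(self):
        df = pd.DataFrame({"A": [1.0, 2], "B": [2.0, 1]})
        with pytest.raises(ValueError, match="'g'"):
            q.pair_scatter_stats(_norm(df, ["g"] * 2), "A", "B", ["g"])
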