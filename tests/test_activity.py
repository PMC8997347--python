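"""Shape clustering, NB differential expression and activity scores."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from shapenet.activity import (
    anova_shape,
    cluster_shapes,
    filter_counts,
    kendall_activity_correlation,
    ks_group_difference,
    module_activity,
    nb_differential_expression,
    regulon_activity,
    size_factors,
)


class TestClusterShapes:
    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        rows, truth = [], []
        for k, c in enumerate(centers):
            for _ in range(15):
                rows.append(c + 0.2 * rng.standard_normal(2))
                truth.append(k)
        df = pd.DataFrame(rows, columns=["f1", "f2"])
        labels = cluster_shapes(df, k=3, restarts=10, seed=1)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_cluster_collects_everything(self):
        df = pd.DataFrame(np.random.default_rng(1).normal(size=(8, 3)))
        labels = cluster_shapes(df, k=1, restarts=3, seed=0)
        assert labels.nunique() == 1

    def test_duplicated_rows_co_assigned(self):
        df = pd.DataFrame([[0.0, 0], [0, 0], [5, 5], [5, 5]],
                          columns=["a", "b"])
        labels = cluster_shapes(df, k=2, restarts=5, seed=0)
        assert labels.iloc[0] == labels.iloc[1]
        assert labels.iloc[2] == labels.iloc[3]

    def test_k_above_rows_rejected(self):
        df = pd.DataFrame([[0.0, 1], [1, 0]])
        with pytest.raises(ValueError):
            cluster_shapes(df, k=3)


class TestFilterCounts:
    def _counts(self):
        rng = np.random.default_rng(2)
        c = rng.poisson(50, size=(100, 14))
        return pd.DataFrame(c, index=[f"g{i}" for i in range(100)],
                            columns=[f"s{j}" for j in range(14)])

    def test_all_zero_gene_removed(self):
        counts = self._counts()
        counts.iloc[0] = 0
        assert "g0" not in filter_counts(counts).index

    def test_boundary_count_of_samples_is_inclusive(self):
        counts = self._counts()
        counts.iloc[1] = 0
        counts.iloc[1, :8] = 1000  # CPM > 0.5 in exactly 8 samples
        assert "g1" in filter_counts(counts, min_samples=8).index

    def test_planted_failures_all_removed(self):
        counts = self._counts()
        counts.iloc[:40] = 0
        out = filter_counts(counts)
        assert len(out) == 60


class TestDifferentialExpression:
    def test_size_factors_neutral_for_equal_libraries(self):
        counts = pd.DataFrame([[10, 10, 10, 10], [20, 20, 20, 20]],
                              index=["a", "b"], columns=list("wxyz"))
        sf = size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_expected_counts_give_zero_lfc(self):
        counts = pd.DataFrame(
            np.tile([100, 100, 100, 100, 100, 100], (20, 1)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(6)],
        )
        res = nb_differential_expression(counts, ["s0", "s1", "s2"],
                                         ["s3", "s4", "s5"])
        assert np.allclose(res["log2fc"], 0.0)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(3)
        r = 1 / 0.05
        counts = rng.negative_binomial(r, r / (r + 100), size=(2000, 14))
        cols = [f"s{j}" for j in range(14)]
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(2000)],
                          columns=cols)
        res = nb_differential_expression(df, cols[:7], cols[7:])
        assert 0.03 <= (res["p"] < 0.05).mean() <= 0.08

    def test_power_on_planted_signal(self):
        rng = np.random.default_rng(4)
        r = 1 / 0.05
        mu = np.full((2000, 14), 100.0)
        mu[:200, :7] *= 2.0
        counts = rng.negative_binomial(r, r / (r + mu))
        cols = [f"s{j}" for j in range(14)]
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(2000)],
                          columns=cols)
        res = nb_differential_expression(df, cols[:7], cols[7:])
        assert (res["fdr"].iloc[:200] < 0.05).mean() >= 0.8

    def test_all_zero_library_rejected(self):
        counts = pd.DataFrame([[0, 5, 5, 5]], index=["g"],
                              columns=list("wxyz"))
        with pytest.raises(ValueError):
            nb_differential_expression(counts, ["w", "x"], ["y", "z"])


class TestRegulonActivity:
    def _stats(self, n=500, seed=5):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.standard_normal(n),
                         index=[f"g{i}" for i in range(n)])

    def test_top_ranked_activated_targets_positive_nes(self):
        stats = self._stats()
        top = set(stats.sort_values(ascending=False).index[:20])
        regs = {"tf": {"activated": top, "repressed": set(),
                       "unknown": set()}}
        out = regulon_activity(stats, regs)
        assert out.loc["tf", "nes"] > 3
        assert out.loc["tf", "p"] < 1e-3

    def test_repressed_targets_flip_sign(self):
        stats = self._stats()
        top = set(stats.sort_values(ascending=False).index[:20])
        act = regulon_activity(stats, {"tf": {"activated": top,
                                              "repressed": set(),
                                              "unknown": set()}})
        rep = regulon_activity(stats, {"tf": {"activated": set(),
                                              "repressed": top,
                                              "unknown": set()}})
        assert rep.loc["tf", "nes"] == pytest.approx(-act.loc["tf", "nes"])

    def test_antisymmetric_under_stat_sign_flip(self):
        stats = self._stats(seed=6)
        regs = {"tf": {"activated": set(stats.index[::9]),
                       "repressed": set(), "unknown": set()}}
        a = regulon_activity(stats, regs).loc["tf", "nes"]
        b = regulon_activity(-stats, regs).loc["tf", "nes"]
        assert a == pytest.approx(-b, abs=1e-9)

    def test_null_nes_standard_normal(self):
        stats = self._stats(1000, seed=7)
        rng = np.random.default_rng(8)
        nes = []
        for _ in range(1000):
            targets = set(rng.choice(stats.index, size=20, replace=False))
            regs = {"tf": {"activated": targets, "repressed": set(),
                           "unknown": set()}}
            nes.append(regulon_activity(stats, regs).loc["tf", "nes"])
        nes = np.asarray(nes)
        assert -0.1 <= nes.mean() <= 0.1
        assert 0.9 <= nes.std() <= 1.1

    def test_module_activity_uses_plus_modes(self):
        stats = self._stats()
        top = list(stats.sort_values(ascending=False).index[:15])
        out = module_activity(stats, {"M1": top})
        assert out.loc["M1", "nes"] > 0


class TestKendall:
    def _frames(self, n=20, seed=9):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        mod = pd.DataFrame({"nes": rng.standard_normal(n),
                            "fdr": np.zeros(n)}, index=idx)
        return idx, mod

    def test_identical_activities_give_tau_one(self):
        _, mod = self._frames()
        out = kendall_activity_correlation(mod, {"tf": mod.copy()})
        assert out.loc["tf", "tau"] == pytest.approx(1.0)

    def test_monotone_transform_preserves_tau(self):
        _, mod = self._frames()
        tf = mod.copy()
        tf["nes"] = np.exp(tf["nes"])
        out = kendall_activity_correlation(mod, {"tf": tf})
        assert out.loc["tf", "tau"] == pytest.approx(1.0)

    def test_insufficient_significant_samples_reported_na(self):
        _, mod = self._frames()
        tf = mod.copy()
        tf["fdr"] = 1.0
        out = kendall_activity_correlation(mod, {"tf": tf})
        assert np.isnan(out.loc["tf", "tau"])
        assert "insufficient" in out.loc["tf", "note"]


class TestKSAndANOVA:
    def test_identical_samples_have_zero_distance(self):
        vals = pd.Series(np.arange(20.0))
        groups = pd.Series(["a"] * 10 + ["b"] * 10)
        groups.index = vals.index = range(20)
        # identical distributions by construction
        vals[10:] = vals[:10].to_numpy()
        out = ks_group_difference(vals, groups)
        assert out["D"].iloc[0] == 0.0

    def test_disjoint_supports_have_distance_one(self):
        vals = pd.Series(np.r_[np.zeros(6), np.ones(6) * 10])
        groups = pd.Series(["a"] * 6 + ["b"] * 6)
        out = ks_group_difference(vals, groups)
        assert out["D"].iloc[0] == 1.0

    def test_shifted_normals_detected(self):
        rng = np.random.default_rng(10)
        hits = 0
        for rep in range(20):
            vals = pd.Series(np.r_[rng.standard_normal(100),
                                   rng.standard_normal(100) + 1.0])
            groups = pd.Series(["a"] * 100 + ["b"] * 100)
            out = ks_group_difference(vals, groups)
            hits += out["p"].iloc[0] < 0.005
        assert hits >= 19

    def test_anova_detects_large_shift_and_tukey_covers_null(self):
        rng = np.random.default_rng(11)
        cells = pd.DataFrame({
            "feat": np.r_[rng.standard_normal(30),
                          rng.standard_normal(30),
                          rng.standard_normal(30) + 5.0],
        }, index=[f"c{i}" for i in range(90)])
        clusters = pd.Series(["A"] * 30 + ["B"] * 30 + ["C"] * 30,
                             index=cells.index)
        table, tukey = anova_shape(cells, clusters)
        assert table["p"].iloc[0] < 1e-6
        ab = tukey["feat"].query("group1 == 'A' and group2 == 'B'")
        assert float(ab["lower"].iloc[0]) < 0 < float(ab["upper"].iloc[0])
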