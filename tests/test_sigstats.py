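"""Population means, group tests, trend test, heterogeneity, bulk projection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal

from pcdissect.sigstats import (
    batch_association_checks,
    bulk_signature_activity,
    dunn_test,
    group_activity_test,
    intratumor_heterogeneity,
    population_means,
    size_factors,
    trend_test,
)


def exact_kruskal_p(groups):
    """Exact Kruskal-Wallis p by enumerating all assignments of the pooled
    values to the observed group sizes."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    obs = kruskal(*groups).statistic
    n = len(pooled)
    stats = []

    def rec(remaining_idx, gi, parts):
        if gi == len(sizes) - 1:
            split = parts + [remaining_idx]
            stats.append(kruskal(*[pooled[list(p)] for p in split]).statistic)
            return
        for comb in itertools.combinations(remaining_idx, sizes[gi]):
            rest = [i for i in remaining_idx if i not in comb]
            rec(rest, gi + 1, parts + [list(comb)])

    rec(list(range(n)), 0, [])
    stats = np.asarray(stats)
    return float(np.mean(stats >= obs - 1e-12))


class TestPopulationMeans:
    def test_constant_activity_zero_sem(self):
        A = np.full((30, 1), 2.0)
        out = population_means(A, ["S1"] * 30, ["normal"] * 30, n_boot=500)
        assert out.loc[0, "mean_activity"] == 2.0
        assert out.loc[0, "sem"] == 0.0

    def test_bootstrap_matches_analytic_sem(self):
        # balanced 0/1 activities, n = 100: SEM ~ SD/sqrt(n) = 0.5/10
        A = np.array([0.0, 1.0] * 50)[:, None]
        out = population_means(A, ["S"] * 100, ["normal"] * 100, n_boot=10_000, seed=1)
        assert out.loc[0, "sem"] == pytest.approx(0.05, abs=0.005)

    def test_seeded_determinism(self):
        A = np.random.default_rng(3).random((50, 2))
        a = population_means(A, ["S"] * 50, ["abn"] * 50, n_boot=1000, seed=7)
        b = population_means(A, ["S"] * 50, ["abn"] * 50, n_boot=1000, seed=7)
        assert (a["sem"] == b["sem"]).all()

    def test_empty_population_omitted(self):
        A = np.ones((10, 1))
        out = population_means(A, ["S"] * 10, ["normal"] * 10)
        assert set(out["population"]) == {"normal"}


class TestGroupTests:
    def test_kw_matches_exact_enumeration(self, rng):
        from pcdissect.sigstats import kruskal_wallis_p

        for _ in range(5):
            groups = [rng.normal(0, 1, 4).round(1), rng.normal(0, 1, 4).round(1),
                      rng.normal(1, 1, 3).round(1)]
            p_impl = kruskal_wallis_p(groups)  # exact path (n = 11)
            p_exact = exact_kruskal_p(groups)
            assert abs(p_impl - p_exact) < 0.02

    def test_null_false_positive_rate(self, rng):
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            vals = rng.normal(0, 1, 24)
            grp = np.repeat(["a", "b", "c"], 8)
            df = pd.DataFrame(
                {"signature": "W1", "group": grp, "mean_activity": vals}
            )
            res = group_activity_test(df, fwer=0.1)
            hits += int(res["significant"].any())
        assert hits / n_sim <= 0.12

    def test_shifted_group_detected(self, rng):
        found = 0
        n_sim = 50
        for _ in range(n_sim):
            a = rng.normal(0, 1, 8)
            b = rng.normal(0, 1, 8)
            c = rng.normal(3, 1, 8)  # 3 pooled SDs up
            df = pd.DataFrame(
                {
                    "signature": "W1",
                    "group": np.repeat(["a", "b", "c"], 8),
                    "mean_activity": np.concatenate([a, b, c]),
                }
            )
            res = group_activity_test(df, fwer=0.1)
            sig_pairs = res[res["significant"]]
            found += int(
                (("c" == sig_pairs["group_a"]) | ("c" == sig_pairs["group_b"])).any()
            )
        assert found / n_sim >= 0.9

    def test_two_groups_fall_back_to_ranksum(self):
        df = pd.DataFrame(
            {
                "signature": "W1",
                "group": ["a"] * 5 + ["b"] * 5,
                "mean_activity": list(range(5)) + list(range(10, 15)),
            }
        )
        res = group_activity_test(df)
        assert len(res) == 1
        assert res.loc[0, "kw_p"] < 0.05

    def test_small_group_excluded(self):
        df = pd.DataFrame(
            {
                "signature": "W1",
                "group": ["a"] * 5 + ["b"] * 5 + ["c"],
                "mean_activity": np.arange(11.0),
            }
        )
        with pytest.warns(UserWarning, match="excluding"):
            res = group_activity_test(df)
        assert set(res["group_a"]) | set(res["group_b"]) == {"a", "b"}

    def test_dunn_bonferroni_divisor(self):
        vals = np.arange(12.0)
        grp = np.repeat(["a", "b", "c"], 4)
        all_pairs = dunn_test(vals, grp, comparisons="all")
        assert len(all_pairs) == 3
        ref = dunn_test(vals, grp, comparisons=[("b", "a"), ("c", "a")])
        assert len(ref) == 2
        assert np.allclose(ref["p_bonferroni"], np.minimum(ref["p_value"] * 2, 1.0))


class TestTrendTest:
    def test_extreme_ordering_minimal_p(self):
        p = trend_test([[1.0], [2.0], [3.0]])
        # maximum statistic; exact two-sided p over 3! orderings = 2/6
        assert p == pytest.approx(2 / 6, abs=1e-12)

    def test_matches_exact_enumeration(self, rng):
        groups = [rng.normal(0, 1, 3), rng.normal(0.5, 1, 3), rng.normal(1, 1, 3)]
        p_exact = trend_test(groups)  # n = 9 <= 12 -> exact path
        p_asym = trend_test(groups, exact_max_n=0)  # force normal approximation
        assert abs(p_exact - p_asym) < 0.1
        assert 0 <= p_exact <= 1

    def test_null_uniformity(self, rng):
        from scipy.stats import kstest

        pvals = [
            trend_test(
                [rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(0, 1, 15)],
                exact_max_n=0,
            )
            for _ in range(500)
        ]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            trend_test([[1, 2], [3, 4]])


class TestHeterogeneity:
    def test_hand_example(self):
        A = np.concatenate([np.zeros(10), np.zeros(10), np.full(10, 9.0)])[:, None]
        labels = np.repeat(["c1", "c2", "c3"], 10)
        res = intratumor_heterogeneity(A, labels)
        # cluster means [0, 0, 9]: population SD 4.243, mean 3 -> CV 1.414
        assert res.cv.iloc[0] == pytest.approx(np.sqrt(2), abs=1e-12)
        assert bool(res.heterogeneous.iloc[0])

    def test_constant_homogeneous(self):
        A = np.full((30, 1), 5.0)
        labels = np.repeat(["c1", "c2", "c3"], 10)
        res = intratumor_heterogeneity(A, labels)
        assert res.cv.iloc[0] == 0.0
        assert not bool(res.heterogeneous.iloc[0])

    def test_single_cluster_flag_false(self):
        with pytest.warns(UserWarning, match="single cluster"):
            res = intratumor_heterogeneity(np.ones((5, 2)), ["c"] * 5)
        assert not res.heterogeneous.any()

    def test_relabeling_invariance(self, rng):
        A = rng.random((60, 3))
        labels = np.repeat(["x", "y", "z"], 20)
        relabeled = np.repeat(["z", "x", "y"], 20)
        a = intratumor_heterogeneity(A, labels)
        b = intratumor_heterogeneity(A, relabeled)
        assert (a.heterogeneous == b.heterogeneous).all()

    def test_private_subclone_signature_flagged(self):
        from pcdissect.ardnmf import normalize_activities_per_cell
        from pcdissect.simulate import SimulationConfig, generate_cohort

        cfg = SimulationConfig(
            seed=77,
            n_samples_per_stage={"MM": 1},
            purity_per_sample=[1.0],
            cells_per_sample=(400, 400),
            n_genes=300,
            k_true=5,
            n_subclones=3,
            planted_degs=(),
        )
        adata, truth = generate_cohort(cfg)
        H = truth.true_H
        A = normalize_activities_per_cell(H, np.maximum(H.sum(axis=0), 1e-9)).T
        res = intratumor_heterogeneity(A, truth.cluster_of_cell)
        # some private signature heterogeneous, the shared normal-program
        # signature (index 0) not
        assert res.heterogeneous.iloc[1:].any()
        assert not res.heterogeneous.iloc[0]


class TestBatchScreen:
    def _meta(self, n):
        return pd.DataFrame(
            {
                "sex": ["F", "M"] * (n // 2),
                "storage": ["fresh"] * (n // 2) + ["frozen"] * (n // 2),
                "batch": [f"b{i % 3}" for i in range(n)],
                "age": np.linspace(40, 70, n),
            },
            index=[f"S{i}" for i in range(n)],
        )

    def test_null_false_positive_rate(self, rng):
        n_samples = 20
        meta = self._meta(n_samples)
        flags, total = 0, 0
        for _ in range(30):
            sample_ids = np.repeat(meta.index.to_numpy(), 15)
            A = rng.random((len(sample_ids), 4))
            out = batch_association_checks(A, sample_ids, meta)
            flags += int(out["flagged"].sum())
            total += len(out)
        assert 0.01 <= flags / total <= 0.09

    def test_perfect_age_correlation(self):
        meta = self._meta(12)
        sample_ids = np.repeat(meta.index.to_numpy(), 5)
        A = np.repeat(meta["age"].to_numpy(), 5)[:, None]
        out = batch_association_checks(A, sample_ids, meta)
        pear = out[(out["test"] == "pearson")]
        assert pear["stat"].iloc[0] == pytest.approx(1.0)
        assert pear["p_value"].iloc[0] < 1e-6

    def test_constant_covariate_skipped(self):
        meta = self._meta(8)
        meta["storage"] = "fresh"
        sample_ids = np.repeat(meta.index.to_numpy(), 3)
        A = np.random.default_rng(0).random((len(sample_ids), 2))
        out = batch_association_checks(A, sample_ids, meta)
        assert "storage" not in set(out["covariate"])


class TestBulkProjection:
    def test_proportional_samples_factor_two(self, rng):
        base = rng.integers(1, 100, 50).astype(float)
        counts = pd.DataFrame({"s1": base, "s2": 2 * base, "s3": base})
        sf = size_factors(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)

    def test_activities_centered(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(40, 6)).astype(float),
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{i}" for i in range(6)],
        )
        act = bulk_signature_activity(counts, ["g0", "g1", "g2"])
        assert act.mean() == pytest.approx(0.0, abs=1e-10)

    def test_negative_correlation_with_purity(self, rng):
        # bulk mixtures of a normal profile (strong normal-signature genes)
        # and an abnormal profile: activity of the signature's genes falls
        # with tumor purity
        genes = [f"g{i}" for i in range(60)]
        sig_genes = genes[:7]
        normal = rng.gamma(2, 50, 60)
        normal[:7] *= 8  # signature genes high in normal cells
        abnormal = rng.gamma(2, 50, 60)
        abnormal[:7] *= 0.2
        purities = np.linspace(0.05, 0.95, 12)
        cols = {}
        for i, rho in enumerate(purities):
            mix = rho * abnormal + (1 - rho) * normal
            cols[f"s{i}"] = rng.poisson(mix)
        counts = pd.DataFrame(cols, index=genes).astype(float)
        act = bulk_signature_activity(counts, sig_genes)
        r = np.corrcoef(act.to_numpy(), purities)[0, 1]
        assert r < 0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            size_factors(pd.DataFrame({"s1": [1.0, 2.0]}))

    def test_missing_genes_rejected(self):
        counts = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g0"])
        with pytest.raises(ValueError):
            bulk_signature_activity(counts, ["nope"])
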