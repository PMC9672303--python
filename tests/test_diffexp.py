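"""Fold-change statistic, within-patient Wilcoxon DE, cross-patient roll-up."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from pcdissect.diffexp import (
    FoldChangeSpec,
    compute_default_offset,
    cross_patient_max_q,
    group_fold_change,
    prepare_pseudosample_tables,
    wilcoxon_rank_sum,
    within_patient_de,
)
from pcdissect.preprocessing import log_normalize, qc_filter_cells
from pcdissect.simulate import PlantedDEG, SimulationConfig, generate_cohort


def exact_ranksum_p(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n, n_a = len(pooled), len(x)
    ranks = rankdata(pooled)
    obs = ranks[:n_a].sum()
    mean = n_a * (n + 1) / 2.0
    stats = [
        ranks[list(idx)].sum() for idx in itertools.combinations(range(n), n_a)
    ]
    stats = np.asarray(stats)
    return float(np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-12))


class TestGroupFoldChange:
    def test_identical_groups_unity(self):
        x = np.array([[0.5, 1.2], [0.7, 0.3]])
        assert np.allclose(group_fold_change(x, x), 1.0)

    def test_hand_value_against_zero_group(self):
        # mean_A = ln 2, group B all-zero, offset 0.126:
        # (2 - 1 + 0.126) / (0 + 0.126) = 1.126 / 0.126
        a = np.full((4, 1), np.log(2.0))
        b = np.zeros((4, 1))
        fc = group_fold_change(a, b, FoldChangeSpec(offset=0.126))
        assert fc == pytest.approx(1.126 / 0.126, rel=1e-12)
        assert fc == pytest.approx(8.937, abs=5e-4)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            group_fold_change(np.zeros((0, 2)), np.ones((3, 2)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 5), min_size=1, max_size=6),
        st.lists(st.floats(0, 5), min_size=1, max_size=6),
    )
    def test_reciprocal_identity(self, a, b):
        a = np.array(a)[:, None]
        b = np.array(b)[:, None]
        assert group_fold_change(a, b) * group_fold_change(b, a) == pytest.approx(1.0)

    def test_default_offset_is_half_min_nonzero(self):
        m = np.array([[0.0, 0.4], [1.2, 0.0]])
        assert compute_default_offset(m) == pytest.approx(0.2)


class TestWilcoxon:
    def test_matches_exact_enumeration_small_groups(self, rng):
        for _ in range(12):
            n_a, n_b = rng.integers(3, 8, 2)
            x = rng.normal(0, 1, int(n_a)).round(1)  # rounding creates ties
            y = rng.normal(0.5, 1, int(n_b)).round(1)
            p_impl = wilcoxon_rank_sum(x[:, None], y[:, None])[0]
            p_exact = exact_ranksum_p(x, y)
            assert abs(p_impl - p_exact) < 0.02

    def test_matches_scipy_asymptotic(self, rng):
        from scipy.stats import mannwhitneyu

        x = rng.normal(0, 1, (30, 5))
        y = rng.normal(0.3, 1, (25, 5))
        p_impl = wilcoxon_rank_sum(x, y)
        for j in range(5):
            p_ref = mannwhitneyu(x[:, j], y[:, j], method="asymptotic").pvalue
            assert p_impl[j] == pytest.approx(p_ref, abs=1e-10)

    def test_all_ties_p_one(self):
        x = np.ones((10, 1))
        y = np.ones((8, 1))
        assert wilcoxon_rank_sum(x, y)[0] == 1.0


def _mixed_sample(seed, planted=(), n_cells=400, purity=0.5, calibration=True):
    """One mixed sample; in calibration mode both populations share the same
    signature mixture, so planted effects are the only systematic DE signal."""
    cfg = SimulationConfig(
        seed=seed,
        n_samples_per_stage={"SMM": 1},
        purity_per_sample=[purity],
        clonal_chain_per_sample=["kappa"],
        cells_per_sample=(n_cells, n_cells),
        n_genes=400,
        k_true=3,
        planted_degs=planted,
        share_population_mixture=calibration,
    )
    adata, truth = generate_cohort(cfg)
    adata = log_normalize(qc_filter_cells(adata))
    labels = np.where(adata.obs["is_abnormal_true"], "abnormal", "normal")
    return adata, truth, labels


def eq6_statistic_oracle(rate, scale, offset, fold=1.0, n_max=400):
    """Expected fold-change statistic for a Poisson gene, by direct summation:
    E[ln(1 + scale * n)] with n ~ Poisson(rate * fold) vs Poisson(rate)."""
    from scipy.stats import poisson

    def mean_lognorm(r):
        n = np.arange(n_max)
        return float(poisson.pmf(n, r) @ np.log1p(scale * n))

    return (np.expm1(mean_lognorm(rate * fold)) + offset) / (
        np.expm1(mean_lognorm(rate)) + offset
    )


class TestWithinPatientDE:
    def test_null_sample_calibrated(self):
        adata, _, labels = _mixed_sample(31)
        tab = within_patient_de(adata, labels, "S")
        frac_sig = (tab["p_value"] < 0.05).mean()
        assert frac_sig <= 0.08
        assert tab["is_deg"].sum() <= max(2, 0.01 * len(tab))

    def test_planted_genes_detected(self):
        adata, truth, labels = _mixed_sample(
            32, planted=(PlantedDEG(40, 2.5, "up", "abnormal"),), n_cells=650
        )
        tab = within_patient_de(adata, labels, "S").set_index("gene")
        planted = [g for g in truth.planted_degs[0]["symbols"] if g in tab.index]
        sens = tab.loc[planted, "is_deg"].mean()
        assert sens >= 0.8
        called = tab[tab["is_deg"] & (tab["log_fold_change"] > 0)].index
        fdr = np.mean([g not in set(planted) for g in called]) if len(called) else 0.0
        assert fdr <= 0.15

    def test_planted_fold_change_matches_statistic_oracle(self):
        # the fold-change statistic is upward-biased for lowly expressed
        # genes (Jensen gap of the log); the oracle predicts the statistic's
        # expectation per gene from the Poisson rates, independently of the
        # implementation under test
        adata, truth, labels = _mixed_sample(
            33, planted=(PlantedDEG(40, 2.0, "up", "abnormal"),), n_cells=650
        )
        tab = within_patient_de(adata, labels, "S").set_index("gene")
        planted = [g for g in truth.planted_degs[0]["symbols"] if g in tab.index]
        observed = np.exp(tab.loc[planted, "log_fold_change"]).median()

        nrm = labels == "normal"
        scale = 1e4 / np.median(adata.obs["n_c"])
        offset = compute_default_offset(adata.layers["lognorm"])
        predictions = []
        for g in planted:
            gi = adata.var_names.get_loc(g)
            rate = float(np.asarray(adata.X[nrm, gi].todense()).mean())
            if rate > 0:
                predictions.append(eq6_statistic_oracle(rate, scale, offset, fold=2.0))
        predicted = np.median(predictions)
        assert observed == pytest.approx(predicted, rel=0.10)
        # and the statistic stays in the right ballpark of the planted truth
        assert 1.5 <= observed <= 3.0

    def test_constant_gene_not_flagged(self):
        adata, _, labels = _mixed_sample(34, n_cells=100)
        tab = within_patient_de(adata, labels, "S")
        # inject: every tested gene with all-tied values must have p = 1;
        # verified via an explicit constant column
        import anndata as ad

        X = np.ones((60, 3))
        toy = ad.AnnData(X=X, var=pd.DataFrame(index=["CONST", "G1", "G2"]))
        toy.layers["lognorm"] = X.copy()
        lab = np.array(["abnormal"] * 30 + ["normal"] * 30)
        t = within_patient_de(toy, lab, "toy")
        assert (t.set_index("gene").loc["CONST", "p_value"]) == 1.0
        assert not t.set_index("gene").loc["CONST", "is_deg"]

    def test_empty_population_skipped(self):
        adata, _, labels = _mixed_sample(35, n_cells=80)
        labels = np.array(["normal"] * adata.n_obs)
        with pytest.warns(UserWarning, match="skipped"):
            out = within_patient_de(adata, labels, "S")
        assert out is None

    def test_bh_flags_invariant_to_gene_order(self):
        adata, _, labels = _mixed_sample(36, n_cells=150)
        tab = within_patient_de(adata, labels, "S")
        perm = np.random.default_rng(1).permutation(adata.n_vars)
        tab2 = within_patient_de(adata[:, perm].copy(), labels, "S")
        merged = tab.set_index("gene").join(
            tab2.set_index("gene"), lsuffix="_a", rsuffix="_b"
        )
        assert (merged["is_deg_a"] == merged["is_deg_b"]).all()
        # q monotone nondecreasing in p
        s = tab.sort_values("p_value")
        assert (np.diff(s["q_value"]) >= -1e-12).all()


class TestPseudosamples:
    def test_column_count_and_sums(self, small_cohort):
        adata, _ = small_cohort
        adata = adata.copy()
        labels = np.where(adata.obs["is_abnormal_true"], "abnormal", "normal")
        counts, design = prepare_pseudosample_tables(adata, labels)
        # one column per nonempty (sample, population)
        expected = 0
        for sid in adata.obs["sample_id"].unique():
            m = adata.obs["sample_id"] == sid
            expected += int((labels[m.to_numpy()] == "abnormal").any())
            expected += int((labels[m.to_numpy()] == "normal").any())
        assert counts.shape[1] == expected
        # summed counts equal brute-force sums for a spot-checked column
        col = design.index[0]
        sid, pop = design.loc[col, "sample_id"], design.loc[col, "population"]
        mask = (adata.obs["sample_id"] == sid).to_numpy() & (labels == pop)
        brute = np.asarray(adata.X[mask].sum(axis=0)).ravel()
        kept_genes = counts.index
        assert np.array_equal(
            counts[col].to_numpy(), brute[[adata.var_names.get_loc(g) for g in kept_genes]]
        )

    def test_missing_nbm_age_imputed(self, small_cohort):
        adata, _ = small_cohort
        labels = np.where(adata.obs["is_abnormal_true"], "abnormal", "normal")
        _, design = prepare_pseudosample_tables(adata, labels)
        assert design["age"].notna().all()
        nbm = design[design["stage"] == "NBM"]
        observed = adata.obs.loc[adata.obs["stage"] == "NBM", ["sample_id", "age"]]
        observed = observed.drop_duplicates("sample_id")["age"]
        assert nbm["age"].max() <= np.nanmax(observed) + 1e-9


class TestCrossPatientMaxQ:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene", "comparison", "log_fold_change", "p_value", "q_value", "is_deg"],
        )

    def test_max_q_times_n_patients(self):
        tab = self._table(
            [
                ["g1", "P1", 1.0, 0.001, 0.01, True],
                ["g1", "P2", 0.8, 0.0001, 0.002, True],
            ]
        )
        out = cross_patient_max_q(tab, 10).set_index(["gene", "direction"])
        assert out.loc[("g1", "up"), "max_q_corrected"] == pytest.approx(0.1)
        assert out.loc[("g1", "up"), "n_patients"] == 2

    def test_single_patient_identity(self):
        tab = self._table([["g1", "P1", -1.0, 0.02, 0.05, True]])
        out = cross_patient_max_q(tab, 1)
        assert out.loc[0, "max_q_corrected"] == pytest.approx(0.05)
        assert out.loc[0, "direction"] == "down"

    def test_capped_at_one(self):
        tab = self._table([["g1", "P1", 1.0, 0.1, 0.2, True]])
        out = cross_patient_max_q(tab, 10)
        assert out.loc[0, "max_q_corrected"] == 1.0

    def test_directions_summarized_separately(self):
        tab = self._table(
            [
                ["g1", "P1", 1.0, 0.01, 0.02, True],
                ["g1", "P2", -1.0, 0.01, 0.03, True],
            ]
        )
        out = cross_patient_max_q(tab, 2)
        assert set(out["direction"]) == {"up", "down"}
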