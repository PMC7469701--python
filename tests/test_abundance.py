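"""NB GLM testing machinery: size factors, parameter recovery, LRT behaviour,
BH correction, and the QC operations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_rand_score, silhouette_score

from csmkd import abundance, simulate
from csmkd.errors import InputError
from csmkd.types import CountMatrix, Sample, SampleDesign

from _oracles import bh_stepup


def _design(n_batches=3, conditions=("injected", "mock")):
    return simulate.make_design(n_batches=n_batches, timepoints=["t1"], conditions=list(conditions))


class TestSizeFactors:
    def test_identical_samples_all_one(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5], "c": [10, 20, 5]}, index=list("xyz"))
        sf = abundance.size_factors(CountMatrix(counts))
        np.testing.assert_allclose(sf, 1.0)

    def test_exact_doubling(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]}, index=list("xyz"))
        sf = abundance.size_factors(CountMatrix(counts))
        assert sf["b"] / sf["a"] == pytest.approx(2.0, abs=1e-9)

    def test_recovers_depth_multipliers(self):
        """Median-of-ratios recovers the simulated per-sample depths within 5%
        on a 2000-gene NB matrix."""
        rng = np.random.default_rng(0)
        base = rng.lognormal(3, 1.2, 2000)
        depths = np.array([1.0, 1.6, 0.5, 1.2])
        mu = np.outer(base, depths)
        counts = rng.poisson(rng.gamma(1 / 0.05, 0.05 * mu))
        cm = CountMatrix(pd.DataFrame(counts, columns=list("abcd")))
        sf = abundance.size_factors(cm)
        expected = depths / np.exp(np.mean(np.log(depths)))
        np.testing.assert_allclose(sf.to_numpy(), expected, rtol=0.05)


class TestNbFit:
    def test_lfc_recovery_unbiased(self):
        """Mean recovered condition effect over replicated simulations is
        within +-0.3 log2 units of the simulated -3."""
        design = _design()
        ests = []
        for s in range(10):
            cm = simulate.simulate_counts(
                design, n_genes=50, libsize=100_000, dispersion=0.05,
                condition_log2fc={"target": -3.0},
                target_batch_log2fc={"b1": 0.0, "b2": 0.8, "b3": -0.7}, seed=s,
            )
            res = abundance.lrt_condition(cm, "target", design)
            ests.append(res.log2_fold_change)
        assert np.mean(ests) == pytest.approx(-3.0, abs=0.3)

    def test_permuted_labels_centered_on_zero(self):
        design = _design()
        cm = simulate.simulate_counts(design, n_genes=30, libsize=50_000, dispersion=0.05, seed=3)
        sf = abundance.size_factors(cm)
        y = cm.counts.loc["g0005"].to_numpy()
        rng = np.random.default_rng(1)
        lfcs = []
        samples = list(design.samples)
        for _ in range(100):
            conds = rng.permutation([s.condition for s in samples])
            d = SampleDesign(tuple(
                Sample(s.sample_id, c, s.batch, s.timepoint, s.replicate)
                for s, c in zip(samples, conds)
            ))
            if len({s.condition for s in d.samples}) < 2:
                continue
            try:
                fit = abundance.fit_nb_glm(y, d, offsets=np.log(sf.to_numpy()))
            except InputError:
                continue
            if fit.converged and fit.log2_fold_change is not None:
                lfcs.append(fit.log2_fold_change)
        assert abs(np.mean(lfcs)) < 0.15

    def test_poisson_limit_matches_poisson_fit(self):
        """With dispersion ~ 0 the NB log-likelihood at the fit agrees with a
        Poisson fit."""
        import statsmodels.api as sm

        design = _design()
        cm = simulate.simulate_counts(design, n_genes=20, libsize=20_000, dispersion=0.0, seed=4)
        y = cm.counts.loc["g0003"].to_numpy()
        X = abundance.design_matrix(design, "batch+condition").to_numpy()
        nb = abundance.fit_nb_glm(y, design, alpha=1e-10)
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert nb.loglik == pytest.approx(pois.llf, abs=1e-2)

    def test_nested_likelihood_dominance(self):
        design = _design()
        cm = simulate.simulate_counts(design, n_genes=40, libsize=50_000, dispersion=0.05, seed=6)
        sf = np.log(abundance.size_factors(cm).to_numpy())
        for g in cm.gene_ids[:20]:
            y = cm.counts.loc[g].to_numpy()
            full = abundance.fit_nb_glm(y, design, "batch+condition", sf)
            red = abundance.fit_nb_glm(y, design, "batch", sf, alpha=full.dispersion)
            if full.converged and red.converged:
                assert full.loglik >= red.loglik - 1e-6


class TestLrt:
    def test_constant_condition_statistic_zero(self):
        design = simulate.make_design(n_batches=3, timepoints=["t1"], conditions=["mock"])
        cm = simulate.simulate_counts(design, n_genes=10, libsize=10_000, seed=7)
        res = abundance.lrt_condition(cm, "g0004", design)
        assert res.lrt_statistic == 0.0
        assert res.p_value == 1.0

    def test_knockdown_detected(self):
        design = _design()
        cm = simulate.simulate_counts(
            design, n_genes=200, libsize=100_000, dispersion=0.05,
            condition_log2fc={"target": -3.0},
            target_batch_log2fc={"b1": 0.0, "b2": 1.0, "b3": -0.5}, seed=8,
        )
        res = abundance.lrt_condition(cm, "target", design)
        assert res.converged
        assert res.p_value < 1e-3
        assert res.lrt_statistic >= 0


class TestVolcano:
    def test_bh_hand_case(self):
        np.testing.assert_allclose(abundance.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_gene_adjusted_equals_raw(self):
        np.testing.assert_allclose(abundance.bh_adjust([0.037]), [0.037])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_bh_matches_stepup_oracle(self, ps):
        np.testing.assert_allclose(abundance.bh_adjust(ps), bh_stepup(ps), atol=1e-12)

    def test_low_count_genes_excluded(self):
        design = _design()
        cm = simulate.simulate_counts(design, n_genes=100, libsize=2_000, dispersion=0.05, seed=9)
        vt = abundance.volcano_table(cm, design, min_mean=5.0)
        assert (vt.status == "low_count").any()
        assert vt.loc[vt.status == "low_count", "p"].isna().all()
        ok = vt[vt.status == "ok"]
        assert (ok.padj >= ok.p - 1e-12).all()

    def test_wald_and_lrt_agree_on_strong_effect(self):
        design = _design()
        cm = simulate.simulate_counts(
            design, n_genes=60, libsize=50_000, dispersion=0.05,
            condition_log2fc={"target": -3.0}, seed=10,
        )
        for method in ("lrt", "wald"):
            vt = abundance.volcano_table(cm, design, method=method)
            assert vt.set_index("gene").loc["target", "p"] < 1e-4


class TestQc:
    def _timepoint_matrix(self, seed=0):
        """12 samples, timepoint effects on many genes dwarf a target-only
        condition effect."""
        rng = np.random.default_rng(seed)
        samples = []
        for tp in ("t1", "t2", "t3"):
            for b in ("b1", "b2"):
                for cond in ("injected", "mock"):
                    samples.append(Sample(f"{cond}_{b}_{tp}", cond, b, tp, 1))
        design = SampleDesign(tuple(samples))
        base = rng.lognormal(3, 1, 400)
        tp_effect = {"t1": 1.0, "t2": 4.0, "t3": 0.25}
        affected = rng.random(400) < 0.5
        cols = {}
        for s in design.samples:
            mu = base.copy()
            mu[affected] *= tp_effect[s.timepoint]
            if s.condition == "injected":
                mu[0] *= 0.2
            cols[s.sample_id] = rng.poisson(rng.gamma(1 / 0.05, 0.05 * mu))
        cm = CountMatrix(pd.DataFrame(cols, index=[f"g{i}" for i in range(400)]))
        return cm, design

    def test_pca_variance_sums_to_100(self):
        cm, _ = self._timepoint_matrix()
        res = abundance.pca_samples(cm)
        assert res.variance_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_pca_separates_constructed_groups(self):
        counts = pd.DataFrame(
            {
                "a1": [100, 50, 10], "a2": [100, 50, 10], "a3": [100, 50, 10],
                "b1": [100, 50, 400], "b2": [100, 50, 400], "b3": [100, 50, 400],
            },
            index=["g1", "g2", "g3"],
        )
        res = abundance.pca_samples(CountMatrix(counts))
        pc1 = res.coordinates["PC1"]
        assert (pc1[:3] * pc1[3:].to_numpy() < 0).all() or (np.sign(pc1[:3]).nunique() == 1)
        assert res.variance_pct[0] > 95

    def test_constant_matrix_flagged_degenerate(self):
        counts = pd.DataFrame(np.full((5, 4), 7), columns=list("abcd"))
        res = abundance.pca_samples(CountMatrix(counts))
        assert res.degenerate

    def test_samples_group_by_timepoint_not_condition(self):
        """Developmental stage dominates the transcriptome: silhouette by
        timepoint exceeds silhouette by condition in PC space."""
        cm, design = self._timepoint_matrix(seed=1)
        res = abundance.pca_samples(cm)
        X = res.coordinates[["PC1", "PC2"]].to_numpy()
        tps = [s.timepoint for s in design.samples]
        conds = [s.condition for s in design.samples]
        assert silhouette_score(X, tps) > silhouette_score(X, conds)

    def test_correlation_self_is_one_and_replicates_high(self):
        design = _design()
        cm = simulate.simulate_counts(design, n_genes=2000, libsize=100_000, dispersion=0.05, seed=11)
        corr = abundance.correlation_qc(cm)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        off = corr.to_numpy()[~np.eye(len(corr), dtype=bool)]
        assert (off > 0.9).all()

    def test_depth_floor_boundary(self):
        counts = pd.DataFrame({"a": [9_999_999], "b": [10_000_000]}, index=["g"])
        ok = abundance.depth_qc(CountMatrix(counts), floor=1e7)
        assert not ok["a"] and ok["b"]

    def test_identical_pair_merges_first(self):
        counts = pd.DataFrame(
            {"a": [10, 20, 30], "b": [10, 20, 30], "c": [90, 10, 4]}, index=list("xyz")
        )
        Z, order = abundance.cluster_samples(CountMatrix(counts))
        first = sorted([order[int(Z[0, 0])], order[int(Z[0, 1])]])
        assert first == ["a", "b"]
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_timepoint_partition_recovered(self):
        cm, design = self._timepoint_matrix(seed=2)
        Z, order = abundance.cluster_samples(cm)
        labels = fcluster(Z, t=3, criterion="maxclust")
        truth = [s.timepoint for s in design.samples]
        assert adjusted_rand_score(truth, labels) == 1.0
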