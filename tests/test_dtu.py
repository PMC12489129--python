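"""Usage filter, beta-binomial tests, stage-wise decisions, DM fits."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from myotime import simulate as sim
from myotime.dtu import test_usage as usage_test
from myotime.dtu import (
    FilterParams,
    _holm,
    classify_die_dynamics,
    filter_features,
    fit_beta_binomial,
    fit_dm,
    run_dtu,
    stagewise_adjust,
    usage_proportions,
)

from conftest import make_cm


class TestFilterParams:
    def test_defaults_match_study_thresholds(self):
        p = FilterParams()
        assert (p.min_samples_feature_expr, p.min_samples_feature_prop,
                p.min_samples_gene_expr) == (18, 18, 18)
        assert (p.min_feature_expr, p.min_feature_prop, p.min_gene_expr) == \
            (5, 0.05, 10)

    def test_validation(self):
        with pytest.raises(ValueError):
            FilterParams(min_samples_feature_expr=-1)
        with pytest.raises(ValueError):
            FilterParams(min_feature_prop=1.5)
        with pytest.raises(ValueError):
            FilterParams(min_gene_expr=-2)


def two_iso_matrix(meta36, first_counts, second=50):
    counts = np.vstack([
        np.asarray(first_counts),
        np.full(36, second),
        np.full(36, 200),
        np.full(36, 200),
    ])
    cm = make_cm(counts, meta36, feature_ids=["a1", "a2", "b1", "b2"])
    t2g = pd.Series({"a1": "gA", "a2": "gA", "b1": "gB", "b2": "gB"})
    return cm, t2g


class TestFilter:
    def test_feature_expr_boundary_18_vs_17(self, meta36):
        row = np.zeros(36, dtype=int)
        row[:18] = 5  # exactly 18 samples at the threshold count
        cm, t2g = two_iso_matrix(meta36, row)
        kept, report = filter_features(cm, t2g)
        assert "a1" in kept.feature_ids

        row17 = np.zeros(36, dtype=int)
        row17[:17] = 5
        cm, t2g = two_iso_matrix(meta36, row17)
        kept, report = filter_features(cm, t2g)
        assert "a1" not in kept.feature_ids
        failed = report.set_index("id")["failed_rule"]
        assert failed["a1"] == "min_samples_feature_expr"

    def test_proportion_rule(self, meta36):
        # expressed everywhere but always under 5% of the gene total
        row = np.full(36, 5, dtype=int)
        cm, t2g = two_iso_matrix(meta36, row, second=200)
        kept, report = filter_features(cm, t2g)
        failed = report.set_index("id")["failed_rule"]
        assert failed["a1"] == "min_samples_feature_prop"

    def test_gene_expr_rule(self, meta36):
        counts = np.vstack([np.full(36, 4), np.full(36, 4),
                            np.full(36, 200), np.full(36, 200)])
        cm = make_cm(counts, meta36, feature_ids=["a1", "a2", "b1", "b2"])
        t2g = pd.Series({"a1": "gA", "a2": "gA", "b1": "gB", "b2": "gB"})
        kept, report = filter_features(cm, t2g)
        # gene total 8 < 10: gA dropped as a gene even though proportions pass
        assert set(kept.feature_ids) == {"b1", "b2"}
        assert "min_samples_gene_expr" in set(report["failed_rule"])

    def test_single_survivor_gene_dropped(self, meta36):
        row = np.zeros(36, dtype=int)
        cm, t2g = two_iso_matrix(meta36, row)
        kept, report = filter_features(cm, t2g)
        assert "a2" not in kept.feature_ids  # lone survivor of gA
        failed = dict(zip(report["id"], report["failed_rule"]))
        assert failed["gA"] == "fewer_than_2_isoforms"

    def test_threshold_above_sample_count_raises(self, tiny_cm):
        t2g = pd.Series("g", index=tiny_cm.feature_ids)
        with pytest.raises(ValueError, match="exceeds"):
            filter_features(tiny_cm, t2g)  # 18 > 12 samples

    def test_no_survivors_raises(self, meta36):
        counts = np.zeros((2, 36), dtype=int)
        counts[:, 0] = [3, 3]
        cm = make_cm(counts, meta36, feature_ids=["a1", "a2"])
        t2g = pd.Series({"a1": "gA", "a2": "gA"})
        with pytest.raises(ValueError, match="survive"):
            filter_features(cm, t2g)


class TestBetaBinomialFit:
    def test_recovers_mean_and_precision(self):
        rng = np.random.default_rng(61)
        n = np.full(400, 500)
        gamma, p = 30.0, 0.3
        probs = rng.beta(gamma * p, gamma * (1 - p), size=400)
        y = rng.binomial(n, probs)
        X = np.ones((400, 1))
        coefs, gam, llf, ok = fit_beta_binomial(
            y.astype(float), n.astype(float), X
        )
        assert ok
        est_p = 1 / (1 + np.exp(-coefs[0]))
        assert est_p == pytest.approx(p, abs=0.02)
        assert gam == pytest.approx(gamma, rel=0.3)


class TestHolm:
    def test_matches_statsmodels(self):
        rng = np.random.default_rng(62)
        p = rng.uniform(size=50)
        expected = multipletests(p, method="holm")[1]
        assert np.allclose(_holm(p), expected)


@pytest.fixture(scope="module")
def switch_dataset():
    design = sim.DesignSpec()
    truth = sim.make_truth(design, 40, seed=71, isoforms_per_gene=2,
                           dtu_fraction=0.2, dtu_swap=0.5, gamma=50.0)
    cm = sim.simulate_counts(design, truth)
    return truth, cm


class TestUsage:
    def test_planted_switches_get_small_p(self, switch_dataset):
        truth, cm = switch_dataset
        iso, gene = usage_test(cm, truth.iso_gene)
        true_g = truth.dtu_flag.index[truth.dtu_flag]
        null_g = truth.dtu_flag.index[~truth.dtu_flag]
        assert (gene.loc[true_g, "p_screen"] < 0.01).all()
        assert gene.loc[null_g, "p_screen"].median() > 0.1

    def test_screening_p_is_sidak_of_min(self, switch_dataset):
        truth, cm = switch_dataset
        iso, gene = usage_test(cm, truth.iso_gene)
        g = gene.index[0]
        members = iso.loc[iso["gene_id"] == g, "p"].dropna()
        expected = 1 - (1 - members.min()) ** len(members)
        assert gene.loc[g, "p_screen"] == pytest.approx(expected)

    def test_stagewise_level_and_confinement(self, switch_dataset):
        truth, cm = switch_dataset
        res, report = run_dtu(cm, truth.iso_gene)
        G = int(res.gene["p_screen"].notna().sum())
        R = int(res.gene["screened"].sum())
        assert res.stage2_level == pytest.approx(0.05 * R / G)
        confirmed_genes = set(res.isoform.loc[res.isoform["confirmed"],
                                              "gene_id"])
        screened_genes = set(res.gene.index[res.gene["screened"]])
        assert confirmed_genes <= screened_genes

    def test_stagewise_on_crafted_frames(self):
        gene = pd.DataFrame(
            {"p_screen": [1e-6, 0.5, 1e-5, np.nan], "n_isoforms": [2, 2, 2, 2]},
            index=["g1", "g2", "g3", "g4"],
        )
        iso = pd.DataFrame(
            {"gene_id": ["g1", "g1", "g2", "g2", "g3", "g3"],
             "p": [1e-7, 1e-7, 0.4, 0.4, 1e-6, 0.9]},
            index=[f"t{i}" for i in range(6)],
        )
        res = stagewise_adjust(gene, iso, alpha=0.05)
        assert list(res.gene["screened"]) == [True, False, True, False]
        assert res.stage2_level == pytest.approx(0.05 * 2 / 3)
        assert res.isoform.loc["t0", "confirmed"]
        assert not res.isoform.loc["t2", "confirmed"]   # unscreened gene
        assert not res.isoform.loc["t5", "confirmed"]   # large member p


class TestDirichletMultinomial:
    def test_recovers_group_proportions(self):
        rng = np.random.default_rng(63)
        pis = {"d0": np.array([0.6, 0.3, 0.1]), "d5": np.array([0.2, 0.3, 0.5])}
        counts, groups = [], []
        for g, pi in pis.items():
            for _ in range(18):
                p = rng.dirichlet(50.0 * pi)
                counts.append(rng.multinomial(800, p))
                groups.append(g)
        est, gamma, ok = fit_dm(np.array(counts).T, np.array(groups))
        assert ok
        for g, pi in pis.items():
            assert np.allclose(est.loc[g], pi, atol=0.05)
        assert gamma == pytest.approx(50.0, rel=0.5)

    def test_multinomial_limit_gives_large_gamma(self):
        rng = np.random.default_rng(64)
        pi = np.array([0.5, 0.5])
        counts = rng.multinomial(1000, pi, size=30).T
        _, gamma, ok = fit_dm(counts, np.array(["a"] * 30))
        assert gamma > 500.0

    def test_rejects_single_isoform(self):
        with pytest.raises(ValueError, match=">=2"):
            fit_dm(np.ones((1, 10)), np.array(["a"] * 10))


class TestUsageProportions:
    def test_per_day_compositions_sum_to_one(self, design):
        truth = sim.make_truth(design, 20, seed=65, isoforms_per_gene=3)
        cm = sim.simulate_counts(design, truth)
        per_sample, per_day = usage_proportions(cm, truth.iso_gene)
        sums = per_day.groupby(truth.iso_gene.loc[per_day.index]).sum()
        assert np.allclose(sums, 1.0, atol=1e-6)


class TestDieDynamics:
    def _traj(self, rows, ids):
        return pd.DataFrame(rows, index=ids, columns=[0, 1, 2, 3])

    def test_rule_examples(self):
        traj = self._traj(
            [[0, 1, 2, 3], [0, 0, -1, -1],       # gI: opposing members
             [0, 2, 4, 6], [0, 0.1, 0.2, 0.3],    # gS: one dominant member
             [0, 1, 2, 3], [0, 1, 2, 3],          # gC: two equal contributors
             [0, 0, 0, 0], [0, 0, 0, 0]],         # gO: no aggregate change
            ["i1", "i2", "s1", "s2", "c1", "c2", "o1", "o2"],
        )
        t2g = pd.Series({"i1": "gI", "i2": "gI", "s1": "gS", "s2": "gS",
                         "c1": "gC", "c2": "gC", "o1": "gO", "o2": "gO"})
        out = classify_die_dynamics(traj, t2g)
        assert out["gI"] == "inverse"
        assert out["gS"] == "single_dominant"
        assert out["gC"] == "cumulative"
        assert out["gO"] == "other"

    def test_single_isoform_gene_is_other(self):
        traj = self._traj([[0, 1, 2, 3]], ["t1"])
        out = classify_die_dynamics(traj, pd.Series({"t1": "g1"}))
        assert out["g1"] == "other"
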