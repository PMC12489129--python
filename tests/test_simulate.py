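"""Generator behavior: determinism, planted truth, distributional sanity."""

import numpy as np
import pandas as pd
import pytest

from myotime import simulate as sim


class TestDesignSpec:
    def test_default_layout(self, design):
        assert design.n_samples == 36
        t = design.sample_table()
        assert len(t) == 36
        assert set(t["cell_line"]) == {"line1", "line2"}
        assert sorted(t["day"].unique()) == [0, 1, 2, 3, 4, 5]
        assert t.groupby(["cell_line", "day"]).size().eq(3).all()

    def test_rejects_degenerate_layouts(self):
        with pytest.raises(ValueError):
            sim.DesignSpec(n_cell_lines=0)
        with pytest.raises(ValueError):
            sim.DesignSpec(days=(0,))


class TestShapeTrajectory:
    def test_templates_start_at_zero(self):
        for lab, tpl in sim.SHAPE_TEMPLATES.items():
            assert tpl[0] == 0.0

    def test_amplitude_scales_linearly(self):
        a = sim.shape_trajectory("Up", (0, 1, 2, 3, 4, 5), 1.0)
        b = sim.shape_trajectory("Up", (0, 1, 2, 3, 4, 5), 3.0)
        assert np.allclose(b, 3 * a)

    def test_mix_needs_rng(self):
        with pytest.raises(ValueError, match="rng"):
            sim.shape_trajectory("Mix", (0, 1, 2, 3, 4, 5), 1.0)

    def test_unknown_label(self):
        with pytest.raises(ValueError, match="unknown"):
            sim.shape_trajectory("Sideways", (0, 1, 2, 3, 4, 5), 1.0)

    def test_template_requires_six_days(self):
        with pytest.raises(ValueError, match="6 days"):
            sim.shape_trajectory("Up", (0, 1, 2), 1.0)


class TestMakeTruth:
    def test_proportions_sum_to_one_per_gene(self, design):
        truth = sim.make_truth(design, 30, seed=3, isoforms_per_gene=3,
                               dtu_fraction=0.5)
        for pi in (truth.pi0, truth.pi1):
            sums = pi.groupby(truth.iso_gene).sum()
            assert np.allclose(sums, 1.0)

    def test_dtu_fraction_respected(self, design):
        truth = sim.make_truth(design, 40, seed=3, isoforms_per_gene=2,
                               dtu_fraction=0.25)
        assert truth.dtu_flag.sum() == 10

    def test_dtu_swap_total_variation(self, design):
        truth = sim.make_truth(design, 40, seed=3, isoforms_per_gene=2,
                               dtu_fraction=0.25, dtu_swap=0.4)
        for g in truth.dtu_flag.index[truth.dtu_flag]:
            members = truth.iso_gene.index[truth.iso_gene == g]
            tv = 0.5 * (truth.pi1[members] - truth.pi0[members]).abs().sum()
            assert tv == pytest.approx(0.4, abs=1e-6)

    def test_proportions_interpolate_then_plateau(self, design):
        truth = sim.make_truth(design, 10, seed=5, isoforms_per_gene=2,
                               dtu_fraction=1.0)
        mid = truth.proportions_at(1)
        expected = truth.pi0 * (2 / 3) + truth.pi1 * (1 / 3)
        pd.testing.assert_series_equal(mid, expected)
        pd.testing.assert_series_equal(truth.proportions_at(3),
                                       truth.proportions_at(5))

    def test_cluster_labels_cycle_through_requested(self, design):
        truth = sim.make_truth(design, 10, seed=1,
                               cluster_labels=("Up", "Down"))
        assert list(truth.cluster_label[:4]) == ["Up", "Down", "Up", "Down"]

    def test_validates_truth_inputs(self, design):
        truth = sim.make_truth(design, 5, seed=1)
        bad_mu = truth.mu.copy()
        bad_mu.iloc[0] = -1.0
        with pytest.raises(ValueError, match="positive"):
            sim.TruthBundle(
                truth.gene_ids, truth.isoform_ids, truth.iso_gene,
                truth.cluster_label, truth.trajectories, truth.dtu_flag,
                truth.pi0, truth.pi1, bad_mu, truth.alpha, truth.delta,
                truth.gamma, truth.seed,
            )


class TestSimulateCounts:
    def test_deterministic_given_seed(self, design):
        a = sim.simulate_counts(design, sim.make_truth(design, 20, seed=9))
        b = sim.simulate_counts(design, sim.make_truth(design, 20, seed=9))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert (a.library_sizes == b.library_sizes).all()

    def test_different_seed_differs(self, design):
        a = sim.simulate_counts(design, sim.make_truth(design, 20, seed=9))
        b = sim.simulate_counts(design, sim.make_truth(design, 20, seed=10))
        assert not a.counts.equals(b.counts)

    def test_flat_gene_means_near_planted_mu(self, design):
        # no DE, no cell-line offset, Poisson noise: sample means track mu
        truth = sim.make_truth(design, 50, seed=12, de_fraction=0.0,
                               delta_sd=0.0, alpha=0.0)
        cm = sim.simulate_counts(design, truth)
        scale = (cm.library_sizes / design.library_size_mean).to_numpy()
        est = (cm.counts.to_numpy() / scale).mean(axis=1)
        rel = est / truth.mu.to_numpy() - 1
        assert np.abs(rel).max() < 0.1

    def test_planted_log2fc_recovered_on_average(self, design):
        truth = sim.make_truth(design, 30, seed=13, cluster_labels=("Up",),
                               amplitude=2.0, delta_sd=0.0, alpha=0.0)
        cm = sim.simulate_counts(design, truth)
        scale = (cm.library_sizes / design.library_size_mean).to_numpy()
        norm = cm.counts.to_numpy() / scale
        d0 = norm[:, (cm.metadata["day"] == 0).to_numpy()].mean(axis=1)
        d5 = norm[:, (cm.metadata["day"] == 5).to_numpy()].mean(axis=1)
        lfc = np.log2(d5 / d0)
        assert np.abs(lfc - 2.0).mean() < 0.25

    def test_gamma_adds_proportion_overdispersion(self, design):
        def rep_prop_sd(gamma):
            truth = sim.make_truth(design, 40, seed=21, isoforms_per_gene=2,
                                   de_fraction=0.0, gamma=gamma)
            cm = sim.simulate_counts(design, truth)
            counts = cm.counts.to_numpy()
            first = np.arange(0, 80, 2)
            tot = counts[first] + counts[first + 1]
            prop = counts[first] / np.where(tot > 0, tot, 1)
            return float(prop.std(axis=1).mean())

        assert rep_prop_sd(5.0) > rep_prop_sd(5000.0) + 0.02


class TestSimulateAnnotation:
    def test_all_reference_when_no_novel(self):
        ann = sim.simulate_annotation(20, novel_fraction=0.0, seed=4)
        assert (ann.truth_category == "FSM").all()
        assert len(ann.reference) == len(ann.transcripts)

    def test_all_nnc_when_everything_novel(self):
        ann = sim.simulate_annotation(20, novel_fraction=1.0, seed=4)
        assert (ann.truth_category == "NNC").all()
        assert ann.reference == []

    def test_mixed_fraction_produces_all_categories(self):
        ann = sim.simulate_annotation(80, novel_fraction=0.4, seed=4)
        assert set(ann.truth_category) == {"FSM", "NIC", "NNC"}

    def test_t2g_covers_all_transcripts(self):
        ann = sim.simulate_annotation(15, novel_fraction=0.3, seed=2)
        assert set(ann.t2g.index) == {t.transcript_id for t in ann.transcripts}

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            sim.simulate_annotation(0)
        with pytest.raises(ValueError):
            sim.simulate_annotation(5, novel_fraction=1.5)
        with pytest.raises(ValueError):
            sim.simulate_annotation(5, isoform_count_law={1: 0.5})


class TestConfidenceTables:
    def test_plddt_separated_by_planted_flag(self):
        iso, _ = sim.simulate_confidence_tables(
            [f"t{i}" for i in range(50)], seed=3
        )
        assert (iso.loc[iso["planted_high"], "mean_plddt"] > 0.7).all()
        assert (iso.loc[~iso["planted_high"], "mean_plddt"] <= 0.7).all()

    def test_iptm_symmetric_with_planted_cliques(self):
        _, iptm = sim.simulate_confidence_tables(["t0"], seed=3)
        arr = iptm.to_numpy()
        assert np.allclose(arr, arr.T)
        assert arr[0, 1] == 0.9 and arr[0, 3] == 0.1


class TestSimulateProfiles:
    def test_noiseless_profiles_are_zscored_templates(self):
        prof = sim.simulate_profiles(["Up"], amplitude=1.0, noise_sd=0.0)
        tpl = sim.SHAPE_TEMPLATES["Up"]
        z = (tpl - tpl.mean()) / tpl.std(ddof=1)
        assert np.allclose(prof.iloc[0].to_numpy(), z)

    def test_deterministic(self):
        labels = ["Up", "Down", "Mix"] * 5
        a = sim.simulate_profiles(labels, seed=8)
        b = sim.simulate_profiles(labels, seed=8)
        pd.testing.assert_frame_equal(a, b)
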