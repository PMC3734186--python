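import filecmp
import os

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cyclepred import evaluate, synthgen
from cyclepred.feature_io import GeneLabels, read_feature_table, read_labels
from cyclepred.pipeline import plr_fitter
from cyclepred.preselect import ttest_select


class TestSimConfig:
    def test_inconsistent_counts_rejected(self):
        with pytest.raises(synthgen.ConfigError):
            synthgen.SimConfig(n_genes=10, n_pos=8, n_neg=8)
        with pytest.raises(synthgen.ConfigError):
            synthgen.scaled_config(effect_size=-1.0)
        with pytest.raises(synthgen.ConfigError):
            synthgen.scaled_config(motif_sparsity=1.5)

    def test_fully_labeled_config_permitted(self):
        cfg = synthgen.SimConfig(
            n_genes=40, n_tfs=6, n_motifs=8, n_pos=20, n_neg=20,
            n_drivers_per_phase=0, seed=0,
        )
        _, labels, _ = synthgen.simulate_dataset(cfg)
        assert labels.unlabeled_genes == []


class TestSimulateDataset:
    def test_same_seed_gives_byte_identical_fixture(self, tmp_path):
        cfg = synthgen.SimConfig(
            n_genes=60, n_tfs=8, n_motifs=12, n_pos=20, n_neg=20, seed=5,
            unlabeled_pos_frac=0.2,
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        synthgen.write_fixture(d1, cfg)
        synthgen.write_fixture(d2, cfg)
        for name in sorted(os.listdir(d1)):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_structure_and_truth_bookkeeping(self, scaled_dataset):
        cfg, matrix, labels, truth = scaled_dataset
        tf_block = matrix.block("tf").values.to_numpy()
        assert (tf_block > 0).all()
        motif_block = matrix.block("motif").values.to_numpy()
        assert (motif_block >= 0).all()
        assert (labels.classes == "pos").sum() == cfg.n_pos
        assert (labels.classes == "neg").sum() == cfg.n_neg
        # every driver feature exists; every true positive has one phase
        assert set(truth.driver_ids) <= set(matrix.feature_ids)
        pos = truth.gene_classes.index[truth.gene_classes == "pos"]
        assert (truth.gene_phases.loc[pos] != "NA").all()
        neg = truth.gene_classes.index[truth.gene_classes == "neg"]
        assert (truth.gene_phases.loc[neg] == "NA").all()

    def test_motif_zero_rate_background(self):
        cfg = synthgen.scaled_config(n_drivers_per_phase=0, seed=3)
        matrix, _, _ = synthgen.simulate_dataset(cfg)
        zeros = matrix.block("motif").values.to_numpy() == 0
        n = zeros.size
        sd = np.sqrt(cfg.motif_sparsity * (1 - cfg.motif_sparsity) / n)
        assert abs(zeros.mean() - cfg.motif_sparsity) < 2 * sd

    def test_motif_zero_rate_with_planting_matches_expectation(self, scaled_dataset):
        cfg, matrix, _, _ = scaled_dataset
        zeros = matrix.block("motif").values.to_numpy() == 0
        expected = synthgen.expected_zero_fraction(cfg)
        sd = np.sqrt(expected * (1 - expected) / zeros.size)
        assert abs(zeros.mean() - expected) < 3 * sd

    def test_planted_drivers_top_ranked_by_t_statistic(self):
        cfg = synthgen.SimConfig(
            n_genes=2100, n_tfs=40, n_motifs=80, n_pos=1000, n_neg=1000,
            n_drivers_per_phase=2, effect_size=3.0, seed=0,
        )
        matrix, labels, truth = synthgen.simulate_dataset(cfg)
        cls = labels.classes
        pos = matrix.values.loc[cls.index[cls == "pos"]].to_numpy()
        neg = matrix.values.loc[cls.index[cls == "neg"]].to_numpy()
        t, _ = stats.ttest_ind(pos, neg, axis=0)
        top10 = set(np.asarray(matrix.feature_ids)[np.argsort(-np.abs(t))[:10]])
        assert set(truth.driver_ids) == top10

    def test_zero_effect_gives_chance_level_cv_auc(self):
        cfg = synthgen.SimConfig(
            n_genes=420, n_tfs=20, n_motifs=40, n_pos=200, n_neg=200,
            effect_size=0.0, seed=9,
        )
        matrix, labels, _ = synthgen.simulate_dataset(cfg)
        sub = matrix.subset_genes(labels.labeled_genes)
        cv = evaluate.kfold_cv(sub, labels.y(), 10, plr_fitter(1.0), seed=9)
        auc = evaluate.roc_auc(cv.binary_scores, cv.labels).auc
        assert abs(auc - 0.5) < 0.05

    def test_cv_auc_non_decreasing_in_effect_size(self):
        sizes = [0.0, 1.5, 3.0]
        means = []
        for effect in sizes:
            aucs = []
            for seed in range(10):
                cfg = synthgen.SimConfig(
                    n_genes=160, n_tfs=20, n_motifs=40, n_pos=60, n_neg=60,
                    effect_size=effect, seed=seed, unlabeled_pos_frac=0.0,
                )
                matrix, labels, _ = synthgen.simulate_dataset(cfg)
                sub = matrix.subset_genes(labels.labeled_genes)
                cv = evaluate.kfold_cv(sub, labels.y(), 3, plr_fitter(1.0), seed=seed)
                aucs.append(evaluate.roc_auc(cv.binary_scores, cv.labels).auc)
            means.append(np.mean(aucs))
        assert means[0] <= means[1] <= means[2]


class TestSimulatePPI:
    def _labels(self, n_pos, n_neg):
        genes = [f"G{i:04d}" for i in range(n_pos + n_neg)]
        cls = pd.Series(["pos"] * n_pos + ["neg"] * n_neg, index=genes, dtype=object)
        return GeneLabels(cls)

    def test_zero_rate_gives_empty_edge_list(self):
        cfg = synthgen.scaled_config(ppi_base_rate=0.0, ppi_pos_enrichment=1.0)
        edges = synthgen.simulate_ppi(self._labels(10, 10), cfg)
        assert len(edges) == 0

    def test_saturated_rate_gives_complete_graph(self):
        cfg = synthgen.scaled_config(ppi_base_rate=1.0, ppi_pos_enrichment=1.0)
        labels = self._labels(6, 6)
        edges = synthgen.simulate_ppi(labels, cfg)
        n = 12
        assert len(edges) == n * (n - 1) // 2
        pairs = {frozenset(p) for p in edges.itertuples(index=False)}
        assert len(pairs) == len(edges)  # no duplicates
        assert all(len(p) == 2 for p in pairs)  # no self loops

    def test_positive_pair_density_enriched(self):
        cfg = synthgen.scaled_config(
            ppi_base_rate=0.01, ppi_pos_enrichment=5.0, seed=21
        )
        labels = self._labels(250, 250)
        edges = synthgen.simulate_ppi(labels, cfg)
        pos = set(labels.classes.index[labels.classes == "pos"])
        pp = sum(1 for a, b in edges.itertuples(index=False) if a in pos and b in pos)
        n_pairs = 250 * 249 // 2
        expected = 0.05
        sd = np.sqrt(expected * (1 - expected) * n_pairs)
        assert abs(pp - expected * n_pairs) < 3 * sd


class TestFixtureRoundTrip:
    def test_fixture_round_trips_through_readers(self, tmp_path):
        cfg = synthgen.SimConfig(
            n_genes=50, n_tfs=6, n_motifs=10, n_pos=15, n_neg=15, seed=2,
            unlabeled_pos_frac=0.25,
        )
        objs = synthgen.write_fixture(tmp_path, cfg)
        tf_back = read_feature_table(tmp_path / "features_tf.tsv")
        motif_back = read_feature_table(tmp_path / "features_motif.tsv")
        pd.testing.assert_frame_equal(tf_back.values, objs["matrix"].block("tf").values)
        pd.testing.assert_frame_equal(
            motif_back.values, objs["matrix"].block("motif").values
        )
        labels_back = read_labels(tmp_path / "labels.tsv")
        pd.testing.assert_series_equal(
            labels_back.classes, objs["labels"].classes, check_names=False
        )
        truth_back = synthgen.read_truth(tmp_path)
        assert truth_back.driver_features == objs["truth"].driver_features

    def test_truth_lists_exactly_the_planted_drivers(self, scaled_dataset):
        cfg, matrix, labels, truth = scaled_dataset
        assert len(truth.driver_features) == cfg.n_drivers_per_phase * 5
        scopes = [s for _, s, _ in truth.driver_features]
        assert scopes.count("global") == cfg.n_drivers_per_phase
        for phase in synthgen.PHASES:
            assert scopes.count(phase) == cfg.n_drivers_per_phase


def test_driver_selection_survives_t_test(scaled_dataset):
    """Planted effect-3 drivers pass the p < 1e-3 pre-selection screen."""
    cfg, matrix, labels, truth = scaled_dataset
    sel = ttest_select(matrix.subset_genes(labels.labeled_genes), labels, 1e-3)
    kept = set(sel.kept)
    assert set(truth.drivers_for("global")) <= kept
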