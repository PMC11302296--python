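"""Splitting arithmetic, the optimization loop and cross-validation plumbing."""

import numpy as np
import pandas as pd
import pytest

from voxhazard.network import NetworkConfig, build_network
from voxhazard.synthetic import SyntheticConfig
from voxhazard.training import (Hyperparameters, PRESETS, SampleRecord,
                                _epoch_lr, cross_validate, evaluate_network,
                                load_manifest, load_synthetic,
                                stratified_split, train)


def _records(n_ones, n_zeros):
    recs = []
    for i in range(n_ones):
        recs.append(SampleRecord(f"p{i}", f"p{i}.cube", f"p{i}e.cube", 1))
    for i in range(n_zeros):
        recs.append(SampleRecord(f"n{i}", f"n{i}.cube", f"n{i}e.cube", 0))
    return recs


TINY_NET = NetworkConfig(in_shape=(8, 8, 8), feature_size=2, filter_size=3,
                         depth=2, final_layer_neurons=4, pooled_size=2)


@pytest.fixture(scope="module")
def tiny_data():
    cfg = SyntheticConfig(n_atoms_range=(3, 5), box_edge=8.0,
                          grid_shape=(8, 8, 8), placement_margin=2.0,
                          min_atom_separation=1.5)
    tr = load_synthetic(cfg, 24, seed=0)
    va = load_synthetic(cfg, 8, seed=24)
    return tr, va


class TestStratifiedSplit:
    def test_exact_per_class_counts(self):
        recs = _records(60, 40)
        tr, va, te = stratified_split(recs, (0.7, 0.2, 0.1), seed=3)
        assert (len(tr), len(va), len(te)) == (70, 20, 10)
        count = lambda part, lab: sum(r.label == lab for r in part)
        assert (count(tr, 1), count(tr, 0)) == (42, 28)
        assert (count(va, 1), count(va, 0)) == (12, 8)
        assert (count(te, 1), count(te, 0)) == (6, 4)

    def test_partition_disjoint_exhaustive(self):
        recs = _records(23, 17)
        tr, va, te = stratified_split(recs, (0.6, 0.25, 0.15), seed=1)
        ids = [r.id for part in (tr, va, te) for r in part]
        assert sorted(ids) == sorted(r.id for r in recs)
        assert len(set(ids)) == len(recs)

    def test_counts_within_one_of_quota(self, rng):
        for trial in range(10):
            n1, n0 = rng.integers(10, 40, 2)
            recs = _records(n1, n0)
            ratios = (0.7, 0.2, 0.1)
            parts = stratified_split(recs, ratios, seed=trial)
            for lab, n in ((1, n1), (0, n0)):
                for part, ratio in zip(parts, ratios):
                    got = sum(r.label == lab for r in part)
                    assert abs(got - ratio * n) < 1.0 + 1e-9

    def test_degenerate_all_train(self):
        recs = _records(5, 5)
        tr, va, te = stratified_split(recs, (1.0, 0.0, 0.0), seed=0)
        assert len(tr) == 10 and not va and not te

    def test_deterministic(self):
        recs = _records(30, 20)
        a = stratified_split(recs, (0.7, 0.2, 0.1), seed=9)
        b = stratified_split(recs, (0.7, 0.2, 0.1), seed=9)
        assert [[r.id for r in part] for part in a] == \
            [[r.id for r in part] for part in b]

    def test_class_smaller_than_partitions(self):
        recs = _records(10, 2)
        with pytest.raises(ValueError, match="fewer than"):
            stratified_split(recs, (0.7, 0.2, 0.1), seed=0)

    def test_bad_ratios(self):
        with pytest.raises(ValueError, match="sum to 1"):
            stratified_split(_records(5, 5), (0.5, 0.2, 0.1), seed=0)


class TestLearningRateSchedule:
    def test_published_step_decay(self):
        hyper = PRESETS["echa"]
        assert hyper.lr_decay == (0.1, 35)
        assert hyper.epochs == 38
        # 0-based epoch 35 is the 36th pass: rate drops to 0.1x
        assert _epoch_lr(hyper, 34) == pytest.approx(hyper.learning_rate)
        assert _epoch_lr(hyper, 35) == pytest.approx(0.1 * hyper.learning_rate)
        assert _epoch_lr(hyper, 37) == pytest.approx(0.1 * hyper.learning_rate)

    def test_no_decay_preset(self):
        hyper = PRESETS["compfood"]
        assert hyper.lr_decay is None
        assert _epoch_lr(hyper, 13) == pytest.approx(hyper.learning_rate)

    def test_presets_reproduce_published_table(self):
        echa, comp = PRESETS["echa"], PRESETS["compfood"]
        assert (echa.epochs, comp.epochs) == (38, 14)
        assert (echa.learning_rate, comp.learning_rate) == (0.000844, 0.0002409)
        assert (echa.batch_size, comp.batch_size) == (20, 12)
        assert (echa.weight_decay, comp.weight_decay) == (2.57e-7, 0.000186)
        assert (echa.feature_size, comp.feature_size) == (28, 4)
        assert (echa.filter_size, comp.filter_size) == (4, 4)
        assert echa.ce_class_weights == (0.65127, 1.34672)
        assert comp.ce_class_weights == (1.24926, 1.1977)
        assert (echa.final_layer_neurons, comp.final_layer_neurons) == (16, 32)


class TestTrainLoop:
    def test_zero_epochs_is_identity(self, tiny_data):
        tr, va = tiny_data
        net = build_network(TINY_NET, seed=0)
        before = {k: v.copy() for k, v in net.state_dict().items()}
        net2, history = train(net, tr, va, Hyperparameters(epochs=0))
        assert history.empty
        for k, v in net2.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_loss_decreases_on_planted_signal(self, tiny_data):
        tr, va = tiny_data
        net = build_network(TINY_NET, seed=0)
        net, history = train(net, tr, va, Hyperparameters(
            epochs=4, learning_rate=3e-3, batch_size=8, seed=0))
        assert history["train_total"].iloc[-1] < history["train_total"].iloc[0]
        assert set(history.columns) >= {"epoch", "lr", "train_ce",
                                        "train_gen_dice", "val_acc"}

    def test_reproducible_histories(self, tiny_data):
        tr, va = tiny_data
        hyper = Hyperparameters(epochs=2, learning_rate=1e-3, batch_size=8,
                                seed=4)
        _, h1 = train(build_network(TINY_NET, seed=4), tr, va, hyper)
        _, h2 = train(build_network(TINY_NET, seed=4), tr, va, hyper)
        pd.testing.assert_frame_equal(h1, h2)

    def test_returns_best_validation_checkpoint(self, tiny_data):
        tr, va = tiny_data
        net, history = train(build_network(TINY_NET, seed=1), tr, va,
                             Hyperparameters(epochs=3, learning_rate=3e-3,
                                             batch_size=8, seed=1))
        rep = evaluate_network(net, va, batch_size=8)
        assert rep.accuracy == pytest.approx(history["val_acc"].max())


class TestCrossValidation:
    def test_two_fold_stratification_on_four_samples(self, tiny_data):
        tr, _ = tiny_data
        labels = tr.labels
        # pick two of each class
        idx = np.concatenate([np.flatnonzero(labels == 0)[:2],
                              np.flatnonzero(labels == 1)[:2]])
        four = tr.subset(idx)
        out = cross_validate(four, Hyperparameters(epochs=1, batch_size=2),
                             TINY_NET, k=2, seed=0, val_fraction=0.5)
        assert len(out["fold_accuracy"]) == 2
        for rep in out["fold_reports"]:
            assert rep.confusion.sum() == 2
            np.testing.assert_array_equal(rep.confusion.sum(axis=1), [1, 1])

    def test_mean_aggregation(self, tiny_data):
        tr, va = tiny_data
        pooled = tr
        out = cross_validate(pooled, Hyperparameters(epochs=1, batch_size=8),
                             TINY_NET, k=3, seed=0)
        assert out["mean_accuracy"] == pytest.approx(
            np.mean(out["fold_accuracy"]))
        assert out["mean_weighted_f1"] == pytest.approx(
            np.mean(out["fold_weighted_f1"]))

    def test_class_smaller_than_k(self, tiny_data):
        tr, _ = tiny_data
        small = tr.subset(np.arange(4))
        with pytest.raises(ValueError, match=">="):
            cross_validate(small, Hyperparameters(epochs=1), TINY_NET, k=5)


class TestManifestLoading:
    def test_manifest_round_trip(self, tiny_synthetic_config, tmp_path):
        from voxhazard.synthetic import generate_dataset
        generate_dataset(4, tiny_synthetic_config, tmp_path)
        records = load_manifest(tmp_path / "manifest.csv")
        assert len(records) == 4
        assert all(r.density_path.exists() for r in records)

    def test_missing_cube_reported(self, tiny_synthetic_config, tmp_path):
        from voxhazard.synthetic import generate_dataset
        generate_dataset(2, tiny_synthetic_config, tmp_path)
        (tmp_path / "mol00001_en.cube").unlink()
        with pytest.raises(FileNotFoundError, match="mol00001_en"):
            load_manifest(tmp_path / "manifest.csv")

    def test_missing_column_reported(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("id,density_path,label\na,b.cube,1\n")
        with pytest.raises(ValueError, match="en_path"):
            load_manifest(path)
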