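"""Split protocol, training loop behaviour, and fold evaluation."""

import numpy as np
import pandas as pd
import pytest

from neurograde import (
    ArchitectureKind,
    AugmentationPolicy,
    NetworkConfig,
    SyntheticSpec,
    TrainConfig,
    stratified_splits,
)
from neurograde.experiment import FoldSplit, evaluate_fold, train_fold
from neurograde.labels import CLASSES
from neurograde.metrics import ClassWeights, compute_class_weights, weighted_cross_entropy
from neurograde.synthetic import generate_samples
from neurograde.volumes import preprocess


def manifest_for(counts: dict[str, int]) -> pd.DataFrame:
    rows = [{"subject_id": f"{label.lower()}_{i}", "label": label}
            for label, n in counts.items() for i in range(n)]
    return pd.DataFrame(rows)


class TestStratifiedSplits:
    def test_study_cohort_counts(self):
        """Class sizes (73, 259, 259) at fraction 0.3 give per-class test
        counts (22, 78, 78): round_half_up(21.9) and round_half_up(77.7)."""
        m = manifest_for({"LGG": 73, "HGG": 259, "HEALTHY": 259})
        splits = stratified_splits(m, n_repeats=3, test_fraction=0.3, seed=0)
        assert len(splits) == 3
        for fold in splits:
            labels = dict(zip(m["subject_id"], m["label"]))
            test_counts = {c: sum(labels[s] == c for s in fold.test_ids) for c in CLASSES}
            assert test_counts == {"LGG": 22, "HGG": 78, "HEALTHY": 78}
            assert len(fold.test_ids) == 178
            assert len(fold.train_ids) == 413

    def test_disjoint_and_exhaustive_on_random_manifests(self, rng):
        for _ in range(100):
            counts = {c: int(rng.integers(4, 40)) for c in CLASSES}
            m = manifest_for(counts)
            for fold in stratified_splits(m, n_repeats=2, test_fraction=0.3,
                                          seed=int(rng.integers(1 << 30))):
                train, test = set(fold.train_ids), set(fold.test_ids)
                assert not train & test
                assert train | test == set(m["subject_id"])

    def test_deterministic_under_seed(self):
        m = manifest_for({"LGG": 10, "HGG": 20, "HEALTHY": 15})
        a = stratified_splits(m, seed=42)
        b = stratified_splits(m, seed=42)
        assert a == b
        c = stratified_splits(m, seed=43)
        assert a != c

    def test_repeats_are_independent_draws(self):
        m = manifest_for({"LGG": 30, "HGG": 30, "HEALTHY": 30})
        splits = stratified_splits(m, n_repeats=3, seed=1)
        assert splits[0].test_ids != splits[1].test_ids

    def test_tiny_class_rejected(self):
        m = manifest_for({"LGG": 1, "HGG": 10, "HEALTHY": 10})
        with pytest.raises(ValueError, match="LGG"):
            stratified_splits(m)

    def test_overlapping_fold_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            FoldSplit(1, ("a", "b"), ("b", "c"), 0)


class TestTrainConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(device="gpu")

    def test_unit_weights_match_plain_cross_entropy(self, rng):
        """With W_c = 1 the weighted loss is the standard cross-entropy."""
        unit = ClassWeights(np.ones(3), np.array([1, 1, 1]))
        logits = rng.normal(size=3)
        lb = weighted_cross_entropy(logits, "HGG", unit)
        logsumexp = np.log(np.exp(logits - logits.max()).sum()) + logits.max()
        direct = -(logits[1] - logsumexp)
        assert lb.total == pytest.approx(direct, abs=1e-6)


@pytest.fixture(scope="module")
def tiny_phantoms():
    """Six small separable phantoms (two per class), preprocessed."""
    spec = SyntheticSpec(
        volume_shape=(32, 32, 32),
        n_per_class={c: 2 for c in CLASSES},
        lgg_radius_range=(4.0, 6.0),
        hgg_radius_range=(4.0, 6.0),
        seed=5,
    )
    return {s.subject_id: preprocess(s) for s in generate_samples(spec)}


class TestTrainFold:
    def test_overfits_tiny_separable_set(self, tiny_phantoms):
        """A width-reduced network reaches training accuracy 1.0 on six
        separable phantoms within 60 epochs."""
        ids = tuple(tiny_phantoms)
        fold = FoldSplit(1, ids, (), 0)
        cfg = NetworkConfig(kind=ArchitectureKind.RESNET_MIXED, base_width=4, seed=3)
        tcfg = TrainConfig(learning_rate=1e-3, epochs=60, seed=3,
                           augmentation=AugmentationPolicy(enabled=False))
        net, history = train_fold(cfg, tcfg, fold, tiny_phantoms)
        assert all(np.isfinite(h) and h >= 0 for h in history)
        train_eval = FoldSplit(2, (), ids, 0)
        cm = evaluate_fold(net, train_eval, tiny_phantoms)
        assert cm.accuracy == 1.0

    def test_loss_history_finite_and_weights_from_train_only(self, tiny_phantoms):
        ids = list(tiny_phantoms)
        fold = FoldSplit(1, tuple(ids[:4]), tuple(ids[4:]), 0)
        train_labels = [tiny_phantoms[s].label for s in fold.train_ids]
        expected = compute_class_weights({c: train_labels.count(c) for c in CLASSES})
        # the same computation inside train_fold must not see the test split
        test_labels = [tiny_phantoms[s].label for s in fold.test_ids]
        assert sorted(train_labels + test_labels) == sorted(
            s.label for s in tiny_phantoms.values()
        )
        cfg = NetworkConfig(kind=ArchitectureKind.RESNET_MIXED, base_width=2, seed=0)
        tcfg = TrainConfig(learning_rate=1e-3, epochs=2, seed=0,
                           augmentation=AugmentationPolicy(enabled=False))
        net, history = train_fold(cfg, tcfg, fold, tiny_phantoms)
        assert len(history) == 2
        assert all(np.isfinite(h) for h in history)
        assert expected.weights.sum() == pytest.approx(2.0)

    def test_tail_weight_averaging(self, tiny_phantoms):
        """Averaging the last epochs' weights is deterministic and differs
        from the final-epoch weights."""
        from neurograde.models import state_dict

        ids = tuple(tiny_phantoms)
        fold = FoldSplit(1, ids, (), 0)
        cfg = NetworkConfig(kind=ArchitectureKind.RESNET_MIXED, base_width=2, seed=0)
        base = dict(learning_rate=1e-3, epochs=3, seed=0,
                    augmentation=AugmentationPolicy(enabled=False))
        net_last, _ = train_fold(cfg, TrainConfig(**base), fold, tiny_phantoms)
        net_avg, _ = train_fold(cfg, TrainConfig(**base, average_last_epochs=3),
                                fold, tiny_phantoms)
        net_avg2, _ = train_fold(cfg, TrainConfig(**base, average_last_epochs=3),
                                 fold, tiny_phantoms)
        last, avg, avg2 = state_dict(net_last), state_dict(net_avg), state_dict(net_avg2)
        assert any(not np.array_equal(last[n], avg[n]) for n in last)
        assert all(np.array_equal(avg[n], avg2[n]) for n in avg)
        with pytest.raises(ValueError):
            TrainConfig(**base, average_last_epochs=9)

    def test_training_is_deterministic_under_seed(self, tiny_phantoms):
        ids = tuple(tiny_phantoms)
        fold = FoldSplit(1, ids, (), 0)
        cfg = NetworkConfig(kind=ArchitectureKind.RESNET_2P1D, base_width=2, seed=1)
        tcfg = TrainConfig(learning_rate=1e-3, epochs=2, seed=9)
        _, h1 = train_fold(cfg, tcfg, fold, tiny_phantoms)
        _, h2 = train_fold(cfg, tcfg, fold, tiny_phantoms)
        assert h1 == h2


class TestRunExperiment:
    def test_writes_reports_and_checkpoints(self, tiny_phantoms, tmp_path):
        from neurograde import run_experiment

        manifest = pd.DataFrame(
            {"subject_id": list(tiny_phantoms),
             "label": [v.label for v in tiny_phantoms.values()]}
        )
        cfg = NetworkConfig(kind=ArchitectureKind.RESNET_MIXED, base_width=2, seed=0)
        tcfg = TrainConfig(learning_rate=1e-3, epochs=1, seed=0,
                           augmentation=AugmentationPolicy(enabled=False))
        report = run_experiment(cfg, tcfg, manifest, volumes=tiny_phantoms,
                                n_repeats=2, test_fraction=0.5, out_dir=tmp_path)
        assert report.n_folds == 2
        assert report.pooled.total == sum(cm.total for cm in report.fold_confusions)
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "confusion_fold1.csv").exists()
        assert (tmp_path / "confusion_fold2.csv").exists()
        assert (tmp_path / "checkpoint_fold1.npz").exists()


class TestEvaluateFold:
    def test_repeated_evaluation_identical(self, tiny_phantoms):
        ids = tuple(tiny_phantoms)
        fold = FoldSplit(1, ids[:3], ids[3:], 0)
        cfg = NetworkConfig(kind=ArchitectureKind.RESNET_MIXED, base_width=2, seed=0)
        tcfg = TrainConfig(learning_rate=1e-3, epochs=1, seed=0)
        net, _ = train_fold(cfg, tcfg, fold, tiny_phantoms)
        cm1 = evaluate_fold(net, fold, tiny_phantoms)
        cm2 = evaluate_fold(net, fold, tiny_phantoms)
        assert np.array_equal(cm1.counts, cm2.counts)
        assert cm1.total == len(fold.test_ids)

    def test_missing_volume_names_subject(self, tiny_phantoms):
        ids = tuple(tiny_phantoms)
        fold = FoldSplit(1, ids[:3], ids[3:] + ("ghost_000",), 0)
        cfg = NetworkConfig(kind=ArchitectureKind.RESNET_MIXED, base_width=2, seed=0)
        tcfg = TrainConfig(learning_rate=1e-3, epochs=1, seed=0)
        net, _ = train_fold(cfg, tcfg, fold, tiny_phantoms)
        with pytest.raises(KeyError, match="ghost_000"):
            evaluate_fold(net, fold, tiny_phantoms)
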