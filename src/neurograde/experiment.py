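"""Training/evaluation protocol: stratified 70/30 repeats, Adam, batch size 1.

The cross-validation scheme is three *independent* stratified random splits
at a 7:3 train:test ratio (not a partitioning k-fold): each repeat draws,
per class, ``round_half_up(0.3 * n_c)`` test subjects.  Each fold trains a
fresh network with the weighted cross-entropy objective -- the class weights
recomputed from that fold's *training* counts only -- using Adam and
single-sample steps with on-the-fly light augmentation, then evaluates the
final-epoch weights on the held-out subjects with no augmentation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .labels import CLASSES, CLASS_TO_INDEX
from .metrics import (
    ConfusionMatrix,
    CrossValReport,
    compute_class_weights,
    confusion,
    weighted_cross_entropy_grad,
)
from .models import Network, NetworkConfig, build_network, save_checkpoint
from .nn import Adam
from .synthetic import DatasetManifest
from .volumes import AugmentationPolicy, VolumeSample, augment, preprocess, read_volume

__all__ = [
    "FoldSplit",
    "TrainConfig",
    "evaluate_fold",
    "load_volumes",
    "run_experiment",
    "stratified_splits",
    "train_fold",
]

log = logging.getLogger("neurograde")


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test subject sets overlap")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; the defaults are the full-scale protocol.

    ``epochs`` is deliberately a knob (no published value exists): 100 is a
    reasonable full-scale default, CPU-scale runs use far fewer.
    """

    learning_rate: float = 1e-5
    weight_decay: float = 1e-3
    batch_size: int = 1
    epochs: int = 100
    adam_betas: tuple[float, float] = (0.9, 0.999)
    #: >1 averages the weights saved at the end of each of the last k epochs
    #: (tail/Polyak averaging); 1 keeps the final-epoch weights.
    average_last_epochs: int = 1
    dropout_p: float = 0.3
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 1 <= self.average_last_epochs <= self.epochs:
            raise ValueError("average_last_epochs must be in [1, epochs]")
        if self.device != "cpu":
            raise ValueError("only device='cpu' is supported")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_splits(manifest: pd.DataFrame | DatasetManifest, n_repeats: int = 3,
                      test_fraction: float = 0.3, seed: int = 0) -> list[FoldSplit]:
    """Independent stratified random train/test splits.

    Per class, the test count is ``round_half_up(test_fraction * n_c)``;
    every class must keep at least one subject on each side.
    """
    frame = manifest.frame if isinstance(manifest, DatasetManifest) else manifest
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    by_class: dict[str, list[str]] = {}
    for sid, label in zip(frame["subject_id"], frame["label"]):
        by_class.setdefault(label, []).append(str(sid))
    for label, ids in by_class.items():
        n = len(ids)
        if n < 2:
            raise ValueError(f"class {label} has only {n} sample(s); need >= 2")
        k = _round_half_up(test_fraction * n)
        if k < 1 or k >= n:
            raise ValueError(
                f"class {label}: test count {k} of {n} leaves an empty side"
            )
    splits = []
    for r, child in enumerate(np.random.SeedSequence(seed).spawn(n_repeats), start=1):
        rng = np.random.default_rng(child)
        train: list[str] = []
        test: list[str] = []
        for label in sorted(by_class, key=lambda l: CLASS_TO_INDEX.get(l, len(CLASSES))):
            ids = list(by_class[label])
            order = rng.permutation(len(ids))
            k = _round_half_up(test_fraction * len(ids))
            test.extend(ids[i] for i in order[:k])
            train.extend(ids[i] for i in order[k:])
        splits.append(FoldSplit(fold_index=r, train_ids=tuple(train),
                                test_ids=tuple(test), seed=seed))
    return splits


def _fold_rngs(tcfg: TrainConfig, fold: FoldSplit):
    ss = np.random.SeedSequence([tcfg.seed, fold.fold_index])
    s_init, s_shuffle, s_aug = ss.spawn(3)
    init_seed = int(s_init.generate_state(1)[0] % (2 ** 31))
    return init_seed, np.random.default_rng(s_shuffle), np.random.default_rng(s_aug)


def calibrate_batchnorm(net: Network, samples) -> Network:
    """Re-estimate every batch-norm layer's running statistics with one
    training-mode sweep over the given (unaugmented) samples.

    With batch size one the exponentially averaged statistics lag behind the
    fast-moving per-sample statistics of the final weights; replacing them
    with plain means over the training set aligns evaluation-mode
    normalization with what the network saw during training.  Weights are
    not touched and the sweep is deterministic.
    """
    from .nn import BatchNorm3d

    bns = [m for _, m in net.named_modules() if isinstance(m, BatchNorm3d)]
    for bn in bns:
        bn.start_stat_refresh()
    for sample in samples:
        net.forward(np.ascontiguousarray(sample.voxels, dtype=np.float32)[None],
                    training=True)
    for bn in bns:
        bn.finish_stat_refresh()
    return net


def train_fold(cfg: NetworkConfig, tcfg: TrainConfig, fold: FoldSplit,
               volumes: Mapping[str, VolumeSample]) -> tuple[Network, list[float]]:
    """Train a fresh network on one fold; returns the network and the
    per-epoch mean training loss.

    Class weights come from the fold's training-split counts only, so the
    test distribution never influences the objective.
    """
    train_labels = [volumes[sid].label for sid in fold.train_ids]
    counts = {c: train_labels.count(c) for c in CLASSES}
    weights = compute_class_weights(counts)
    init_seed, shuffle_rng, aug_rng = _fold_rngs(tcfg, fold)
    net = build_network(replace(cfg, dropout_p=tcfg.dropout_p, seed=init_seed))
    opt = Adam(net.parameters(), lr=tcfg.learning_rate,
               weight_decay=tcfg.weight_decay, betas=tcfg.adam_betas)
    history: list[float] = []
    ids = list(fold.train_ids)
    # tail averaging: accumulate end-of-epoch weight snapshots over the last
    # k epochs; with single-sample steps the per-epoch endpoint is noisy and
    # the average is a far more stable estimate of the converged weights
    avg_from = tcfg.epochs - tcfg.average_last_epochs
    avg_sum: dict[str, np.ndarray] | None = None
    for epoch in range(tcfg.epochs):
        order = shuffle_rng.permutation(len(ids))
        losses = []
        for start in range(0, len(ids), tcfg.batch_size):
            chunk = order[start:start + tcfg.batch_size]
            opt.zero_grad()
            batch_loss = 0.0
            for j in chunk:
                sample = volumes[ids[j]]
                if tcfg.augmentation.enabled:
                    sample = augment(sample, tcfg.augmentation, aug_rng)
                x = np.ascontiguousarray(sample.voxels, dtype=np.float32)[None]
                logits = net.forward(x, training=True)
                breakdown, grad = weighted_cross_entropy_grad(
                    logits[None], [sample.label], weights
                )
                if not np.isfinite(breakdown.total):
                    raise RuntimeError(
                        f"non-finite loss at fold {fold.fold_index}, epoch {epoch + 1}, "
                        f"subject {ids[j]}: {breakdown.total}"
                    )
                net.backward((grad[0] / len(chunk)).astype(np.float32))
                batch_loss += breakdown.total / len(chunk)
            opt.step()
            losses.append(batch_loss)
        history.append(float(np.mean(losses)))
        log.debug("fold %d epoch %d/%d mean loss %.4f",
                  fold.fold_index, epoch + 1, tcfg.epochs, history[-1])
        if epoch >= avg_from:
            if avg_sum is None:
                avg_sum = {n: p.value.astype(np.float64) for n, p in net.named_parameters()}
            else:
                for n, p in net.named_parameters():
                    avg_sum[n] += p.value
    if avg_sum is not None and tcfg.average_last_epochs > 1:
        for n, p in net.named_parameters():
            p.value[...] = (avg_sum[n] / tcfg.average_last_epochs).astype(p.value.dtype)
    return net, history


def evaluate_fold(net: Network, fold: FoldSplit,
                  volumes: Mapping[str, VolumeSample]) -> ConfusionMatrix:
    """Argmax predictions on the fold's test subjects, no augmentation."""
    true, pred = [], []
    for sid in fold.test_ids:
        if sid not in volumes:
            raise KeyError(f"volume for subject '{sid}' not found")
        sample = volumes[sid]
        logits = net.forward(
            np.ascontiguousarray(sample.voxels, dtype=np.float32)[None], training=False
        )
        true.append(sample.label)
        pred.append(CLASSES[int(np.argmax(logits))])
    return confusion(true, pred)


def load_volumes(manifest: DatasetManifest, do_preprocess: bool = True,
                 target_mm: float = 2.0) -> dict[str, VolumeSample]:
    """Read every manifest volume (joining labels), optionally preprocessed."""
    volumes: dict[str, VolumeSample] = {}
    for row in manifest.frame.itertuples(index=False):
        sample = read_volume(manifest.root / row.path)
        sample.subject_id = str(row.subject_id)
        sample.label = row.label
        if do_preprocess:
            sample = preprocess(sample, target_mm=target_mm)
        volumes[sample.subject_id] = sample
    return volumes


def run_experiment(cfg: NetworkConfig, tcfg: TrainConfig,
                   manifest: pd.DataFrame | DatasetManifest,
                   volumes: Mapping[str, VolumeSample] | None = None,
                   n_repeats: int = 3, test_fraction: float = 0.3,
                   out_dir=None) -> CrossValReport:
    """Train and evaluate all repeats from scratch and assemble the report.

    ``volumes`` may be supplied directly (already preprocessed, keyed by
    subject id); otherwise they are read from the manifest's directory and
    preprocessed.  With ``out_dir`` set, writes ``report.json``, one
    ``confusion_fold{k}.csv`` per fold, and per-fold checkpoints.
    """
    if volumes is None:
        if not isinstance(manifest, DatasetManifest):
            raise ValueError("pass a DatasetManifest or provide volumes explicitly")
        volumes = load_volumes(manifest)
    frame = manifest.frame if isinstance(manifest, DatasetManifest) else manifest
    splits = stratified_splits(frame, n_repeats=n_repeats,
                               test_fraction=test_fraction, seed=tcfg.seed)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    fold_confusions = []
    for fold in splits:
        log.info("fold %d: %d train / %d test subjects",
                 fold.fold_index, len(fold.train_ids), len(fold.test_ids))
        net, history = train_fold(cfg, tcfg, fold, volumes)
        cm = evaluate_fold(net, fold, volumes)
        log.info("fold %d: accuracy %.4f (final train loss %.4f)",
                 fold.fold_index, cm.accuracy, history[-1])
        fold_confusions.append(cm)
        if out_path is not None:
            cm.to_csv(out_path / f"confusion_fold{fold.fold_index}.csv")
            save_checkpoint(net, out_path / f"checkpoint_fold{fold.fold_index}.npz")
    report = CrossValReport(fold_confusions=fold_confusions)
    if out_path is not None:
        (out_path / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return report
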