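"""Dataset handling, stratified splitting, the optimization loop and k-fold CV.

The published training configurations for the two real datasets (a cosmetics
regulatory subset and a compiled food-safety set) ship as presets "echa" and
"compfood". The optimizer is adaptive moment estimation with decoupled
weight decay; the weight-decay preset values plug into it directly. Plain
momentum descent is available via ``Hyperparameters.optimizer``.

Each density grid is scaled before entering the network (by its own
maximum by default; log compression and fixed scales are available), and
grids whose shape differs from the network's input shape are resampled by
trilinear interpolation. Ternary masks are recomputed from the (possibly
resampled) electronegativity grids at load time, so the segmentation
targets always live on the network's grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold

from . import synthetic as syn
from .cube import read_cube
from .evaluation import (EvaluationReport, average_dice, chance_baseline,
                         classification_report, confusion_matrix)
from .losses import LossWeights, generalized_dice_loss, weighted_cross_entropy
from .masking import ternary_mask
from .network import HazardNet, NetworkConfig, build_network
from .nn import SGD, AdamW

__all__ = [
    "SampleRecord",
    "Hyperparameters",
    "PRESETS",
    "LoadedDataset",
    "load_manifest",
    "load_records",
    "load_synthetic",
    "stratified_split",
    "train",
    "evaluate_network",
    "cross_validate",
]


@dataclass(frozen=True)
class SampleRecord:
    """One molecule: identifiers, cube paths, binary hazard label."""

    id: str
    density_path: Path
    en_path: Path
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass(frozen=True)
class Hyperparameters:
    epochs: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 8
    lr_decay: Optional[Tuple[float, int]] = None  # (factor, every_n_epochs)
    weight_decay: float = 0.0
    feature_size: int = 4
    filter_size: int = 3
    ce_class_weights: Tuple[float, float] = (1.0, 1.0)
    final_layer_neurons: int = 16
    seed: int = 0
    optimizer: str = "adamw"  # adamw | sgd
    augment: bool = False  # random cube symmetries (rotations/reflections)

    def __post_init__(self):
        if self.epochs < 0 or self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("epochs >= 0, learning_rate > 0, batch_size >= 1 required")
        if self.optimizer not in ("adamw", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


# Published configurations for the two real-data use-cases.
PRESETS: dict[str, Hyperparameters] = {
    "echa": Hyperparameters(
        epochs=38, learning_rate=0.000844, batch_size=20, lr_decay=(0.1, 35),
        weight_decay=2.57e-7, feature_size=28, filter_size=4,
        ce_class_weights=(0.65127, 1.34672), final_layer_neurons=16,
    ),
    "compfood": Hyperparameters(
        epochs=14, learning_rate=0.0002409, batch_size=12, lr_decay=None,
        weight_decay=0.000186, feature_size=4, filter_size=4,
        ce_class_weights=(1.24926, 1.1977), final_layer_neurons=32,
    ),
}


@dataclass
class LoadedDataset:
    """In-memory training arrays for a set of molecules."""

    inputs: np.ndarray  # (N, C, D, H, W) float32, scaled per the loader's mode
    masks: np.ndarray  # (N, D, H, W) int8 ternary labels
    labels: np.ndarray  # (N,) int
    ids: list[str]

    def __len__(self) -> int:
        return self.labels.shape[0]

    def subset(self, idx) -> "LoadedDataset":
        idx = np.asarray(idx)
        return LoadedDataset(
            self.inputs[idx], self.masks[idx], self.labels[idx],
            [self.ids[i] for i in idx],
        )


def load_manifest(path) -> list[SampleRecord]:
    """Read a manifest CSV (id,density_path,en_path,label); relative paths
    resolve against the manifest's own directory; files must exist."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"id", "density_path", "en_path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    base = path.parent
    records = []
    for row in df.itertuples(index=False):
        dp = base / row.density_path if not Path(row.density_path).is_absolute() else Path(row.density_path)
        ep = base / row.en_path if not Path(row.en_path).is_absolute() else Path(row.en_path)
        for p in (dp, ep):
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing cube file {p}")
        records.append(SampleRecord(str(row.id), dp, ep, int(row.label)))
    return records


def _normalize(values: np.ndarray, mode: float | str = "max") -> np.ndarray:
    """Input scaling for network consumption.

    "max"   — divide by the grid's own peak (default);
    "log1p" — log(1 + v): compresses the dynamic range of sharply peaked
              fields so far-field structure stays visible to convolutions,
              while preserving peak-amplitude ordering across molecules;
    "cbrt"  — cube root of the peak-normalized field;
    number  — divide by that fixed physical scale.
    """
    if mode == "max":
        peak = values.max()
        return values / peak if peak > 0 else values
    if mode == "log1p":
        return np.log1p(np.maximum(values, 0.0))
    if mode == "cbrt":
        peak = values.max()
        return np.cbrt(values / peak) if peak > 0 else values
    return values / float(mode)


def _resample(values: np.ndarray, target_shape: Tuple[int, int, int]) -> np.ndarray:
    if tuple(values.shape) == tuple(target_shape):
        return values
    zoom = [t / s for t, s in zip(target_shape, values.shape)]
    return ndimage.zoom(values, zoom, order=1)


def load_records(
    records: Sequence[SampleRecord],
    in_shape: Tuple[int, int, int] = (32, 32, 32),
    percentiles: Tuple[float, float] = (10.0, 90.0),
    two_channel: bool = False,
    normalize: float | str = "max",
) -> LoadedDataset:
    """Read cube pairs, resample to the network grid and build targets."""
    inputs, masks, labels, ids = [], [], [], []
    for rec in records:
        _, dens = read_cube(rec.density_path)
        _, en = read_cube(rec.en_path)
        d = _resample(dens.values, in_shape)
        e = _resample(en.values, in_shape)
        mask = ternary_mask(en.with_values(e), *percentiles)
        chan = [_normalize(d, normalize)]
        if two_channel:
            chan.append(_normalize(e - e.min(), normalize if normalize == "max" else 4.0))
        inputs.append(np.stack(chan))
        masks.append(mask.labels)
        labels.append(rec.label)
        ids.append(rec.id)
    return LoadedDataset(
        np.asarray(inputs, dtype=np.float32),
        np.asarray(masks, dtype=np.int8),
        np.asarray(labels, dtype=int),
        ids,
    )


def load_synthetic(
    config: syn.SyntheticConfig,
    n_samples: int,
    seed: int | None = None,
    percentiles: Tuple[float, float] = (10.0, 90.0),
    two_channel: bool = False,
    in_shape: Optional[Tuple[int, int, int]] = None,
    normalize: float | str = "max",
) -> LoadedDataset:
    """Generate a synthetic dataset straight into memory (no cube files).

    ``in_shape`` resamples the generated fields to the network grid (same
    trilinear path as for cubes read from disk) before mask computation.
    """
    base = config.seed if seed is None else seed
    target = tuple(in_shape) if in_shape is not None else tuple(config.grid_shape)
    inputs, masks, labels, ids = [], [], [], []
    for i in range(n_samples):
        sample = syn.generate_sample(config, base + i)
        d = _resample(sample.density.values, target)
        e = _resample(sample.electronegativity.values, target)
        mask = ternary_mask(sample.electronegativity.with_values(e), *percentiles)
        chan = [_normalize(d, normalize)]
        if two_channel:
            chan.append(_normalize(e - e.min(), normalize if normalize == "max" else 4.0))
        inputs.append(np.stack(chan))
        masks.append(mask.labels)
        labels.append(sample.label)
        ids.append(f"syn{base + i:06d}")
    return LoadedDataset(
        np.asarray(inputs, dtype=np.float32),
        np.asarray(masks, dtype=np.int8),
        np.asarray(labels, dtype=int),
        ids,
    )


def stratified_split(
    records: Sequence, ratios: Tuple[float, float, float], seed: int = 0
) -> tuple[list, list, list]:
    """Three-way stratified partition with largest-remainder rounding per class.

    Within each class the three part sizes are the ratio quotas rounded so
    they sum exactly to the class size; every count is within one sample of
    its exact quota. Deterministic per seed.
    """
    ratios = tuple(float(r) for r in ratios)
    if any(r < 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-6:
        raise ValueError("ratios must be non-negative and sum to 1")
    labels = np.array([r.label for r in records])
    rng = np.random.default_rng(seed)
    parts: tuple[list, list, list] = ([], [], [])
    n_parts_needed = sum(r > 0 for r in ratios)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_parts_needed:
            raise ValueError(
                f"class {cls} has {len(idx)} samples, fewer than the "
                f"{n_parts_needed} non-empty partitions"
            )
        rng.shuffle(idx)
        quotas = np.array(ratios) * len(idx)
        base = np.floor(quotas).astype(int)
        remainder = len(idx) - base.sum()
        order = np.argsort(-(quotas - base), kind="stable")
        for j in order[:remainder]:
            base[j] += 1
        splits = np.split(idx, np.cumsum(base)[:-1])
        for part, s in zip(parts, splits):
            part.extend(records[i] for i in s)
    return parts


def _loss_weights(hyper: Hyperparameters) -> LossWeights:
    return LossWeights(ce_class_weights=hyper.ce_class_weights)


def _random_cube_symmetry(inputs: np.ndarray, masks: np.ndarray,
                          rng: np.random.Generator):
    """Apply one random element of the cube's 48 symmetries to a batch.

    Inputs are (N, C, D, H, W), masks (N, D, H, W); the same spatial
    transform is applied to both so segmentation targets stay aligned.
    Valid because the fields live on a cubic grid and the planted class
    signal is invariant under rotations and reflections.
    """
    perm = rng.permutation(3)
    flips = rng.integers(0, 2, 3)
    in_axes = tuple(2 + perm)
    mk_axes = tuple(1 + perm)
    inputs = np.transpose(inputs, (0, 1) + in_axes)
    masks = np.transpose(masks, (0,) + mk_axes)
    flip_in = tuple(2 + i for i in range(3) if flips[i])
    flip_mk = tuple(1 + i for i in range(3) if flips[i])
    if flip_in:
        inputs = np.flip(inputs, axis=flip_in)
        masks = np.flip(masks, axis=flip_mk)
    return np.ascontiguousarray(inputs), np.ascontiguousarray(masks)


def _epoch_lr(hyper: Hyperparameters, epoch: int) -> float:
    """Learning rate for 0-based epoch index under the step decay schedule."""
    if hyper.lr_decay is None:
        return hyper.learning_rate
    factor, every = hyper.lr_decay
    return hyper.learning_rate * factor ** (epoch // every)


def _forward_losses(network: HazardNet, data: LoadedDataset, idx, weights: LossWeights):
    seg_scores, class_scores = network(data.inputs[idx])
    ce = weighted_cross_entropy(class_scores, data.labels[idx], weights)
    dice = generalized_dice_loss(seg_scores, data.masks[idx], weights.epsilon)
    return ce, dice, class_scores


def _eval_pass(network: HazardNet, data: LoadedDataset, weights: LossWeights,
               batch_size: int) -> tuple[float, float, float]:
    """(ce, dice, accuracy) over a dataset in evaluation mode."""
    from . import autodiff as ad
    network.eval()
    ces, dices, correct = [], [], 0
    for start in range(0, len(data), batch_size):
        idx = np.arange(start, min(start + batch_size, len(data)))
        with ad.no_grad():
            ce, dice, class_scores = _forward_losses(network, data, idx, weights)
        ces.append(float(ce.data) * len(idx))
        dices.append(float(dice.data) * len(idx))
        correct += int((class_scores.data.argmax(axis=1) == data.labels[idx]).sum())
    network.train()
    n = len(data)
    return sum(ces) / n, sum(dices) / n, correct / n


def train(
    network: HazardNet,
    train_data: LoadedDataset | Sequence[SampleRecord],
    val_data: LoadedDataset | Sequence[SampleRecord],
    hyper: Hyperparameters,
    verbose: bool = False,
) -> tuple[HazardNet, pd.DataFrame]:
    """Optimize the network; return it at its best-validation-accuracy state.

    Mini-batches are reshuffled every epoch from a (seed, epoch) derived
    stream, so runs are reproducible and resumable. History carries the
    per-epoch loss components and accuracies for both sets.
    """
    cfg = network.config
    if not isinstance(train_data, LoadedDataset):
        train_data = load_records(train_data, cfg.in_shape, two_channel=cfg.two_channel_input)
    if not isinstance(val_data, LoadedDataset):
        val_data = load_records(val_data, cfg.in_shape, two_channel=cfg.two_channel_input)
    if len(train_data) == 0 or len(val_data) == 0:
        raise ValueError("train and validation sets must be non-empty")
    weights = _loss_weights(hyper)
    history: list[dict] = []
    if hyper.epochs == 0:
        return network, pd.DataFrame(history)

    params = list(network.parameters())
    if hyper.optimizer == "adamw":
        opt = AdamW(params, lr=hyper.learning_rate, weight_decay=hyper.weight_decay)
    else:
        opt = SGD(params, lr=hyper.learning_rate, weight_decay=hyper.weight_decay)

    best_state = network.state_dict()
    best_acc = -1.0
    network.train()
    for epoch in range(hyper.epochs):
        opt.lr = _epoch_lr(hyper, epoch)
        rng = np.random.default_rng([hyper.seed, epoch])
        order = rng.permutation(len(train_data))
        ce_sum = dice_sum = 0.0
        correct = 0
        for start in range(0, len(order), hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            opt.zero_grad()
            if hyper.augment:
                aug_in, aug_mk = _random_cube_symmetry(
                    train_data.inputs[idx], train_data.masks[idx], rng)
                seg_scores, class_scores = network(aug_in)
                ce = weighted_cross_entropy(class_scores, train_data.labels[idx], weights)
                dice = generalized_dice_loss(seg_scores, aug_mk, weights.epsilon)
            else:
                ce, dice, class_scores = _forward_losses(network, train_data, idx, weights)
            total = ce + dice
            if not np.isfinite(total.data):
                bad = [train_data.ids[i] for i in idx]
                raise RuntimeError(f"non-finite loss at epoch {epoch}, batch ids {bad}")
            total.backward()
            opt.step()
            ce_sum += float(ce.data) * len(idx)
            dice_sum += float(dice.data) * len(idx)
            correct += int((class_scores.data.argmax(axis=1) == train_data.labels[idx]).sum())
        val_ce, val_dice, val_acc = _eval_pass(network, val_data, weights, hyper.batch_size)
        n = len(train_data)
        history.append({
            "epoch": epoch,
            "lr": opt.lr,
            "train_ce": ce_sum / n,
            "train_gen_dice": dice_sum / n,
            "train_total": (ce_sum + dice_sum) / n,
            "train_acc": correct / n,
            "val_ce": val_ce,
            "val_gen_dice": val_dice,
            "val_total": val_ce + val_dice,
            "val_acc": val_acc,
        })
        if verbose:
            print(
                f"epoch {epoch:3d}  loss {(ce_sum + dice_sum) / n:.4f}  "
                f"train_acc {correct / n:.3f}  val_acc {val_acc:.3f}",
                flush=True,
            )
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = network.state_dict()
    network.load_state_dict(best_state)
    return network, pd.DataFrame(history)


def evaluate_network(
    network: HazardNet,
    data: LoadedDataset | Sequence[SampleRecord],
    batch_size: int = 16,
) -> EvaluationReport:
    """Full evaluation: confusion, metrics, chance baseline, per-class dice."""
    cfg = network.config
    if not isinstance(data, LoadedDataset):
        data = load_records(data, cfg.in_shape, two_channel=cfg.two_channel_input)
    from . import autodiff as ad
    network.eval()
    preds, mask_preds = [], []
    for start in range(0, len(data), batch_size):
        idx = np.arange(start, min(start + batch_size, len(data)))
        with ad.no_grad():
            seg_scores, class_scores = network(data.inputs[idx])
        preds.append(class_scores.data.argmax(axis=1))
        mask_preds.append(seg_scores.data.argmax(axis=1).astype(np.int8))
    y_pred = np.concatenate(preds)
    masks_pred = np.concatenate(mask_preds)
    cm = confusion_matrix(data.labels, y_pred)
    dice = average_dice(masks_pred, data.masks)
    return classification_report(cm, chance=chance_baseline(data.labels), dice=dice)


def cross_validate(
    data: LoadedDataset | Sequence[SampleRecord],
    hyper: Hyperparameters,
    network_config: NetworkConfig,
    k: int = 5,
    seed: int = 0,
    val_fraction: float = 0.15,
) -> dict:
    """Stratified k-fold CV: one fresh network per fold.

    Each fold's training portion donates ``val_fraction`` (stratified) for
    model selection. Returns per-fold reports plus unweighted means of
    accuracy and weighted F1.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not isinstance(data, LoadedDataset):
        data = load_records(data, network_config.in_shape,
                            two_channel=network_config.two_channel_input)
    counts = np.bincount(data.labels, minlength=2)
    if counts.min() < k:
        raise ValueError(f"every class needs >= {k} members, got {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports: list[EvaluationReport] = []
    accs, wf1s = [], []
    for fold, (train_idx, test_idx) in enumerate(
        skf.split(np.zeros(len(data)), data.labels)
    ):
        fold_train = data.subset(train_idx)

        class _Rec:  # adapter so stratified_split sees .label
            def __init__(self, i, label):
                self.i, self.label = i, label

        recs = [_Rec(i, int(l)) for i, l in enumerate(fold_train.labels)]
        if np.bincount(fold_train.labels, minlength=2).min() >= 2:
            tr, va, _ = stratified_split(
                recs, (1 - val_fraction, val_fraction, 0.0),
                seed=seed + 1000 + fold)
            inner_train = fold_train.subset([r.i for r in tr])
            inner_val = fold_train.subset([r.i for r in va])
        else:
            # too few members to stratify an inner split: select on fit data
            inner_train = inner_val = fold_train
        net = build_network(network_config, seed=hyper.seed + fold)
        net, _hist = train(
            net, inner_train, inner_val, replace(hyper, seed=hyper.seed + fold),
        )
        report = evaluate_network(net, data.subset(test_idx), hyper.batch_size)
        fold_reports.append(report)
        accs.append(report.accuracy)
        wf1s.append(report.weighted[2])
    return {
        "fold_reports": fold_reports,
        "fold_accuracy": accs,
        "fold_weighted_f1": wf1s,
        "mean_accuracy": float(np.mean(accs)),
        "mean_weighted_f1": float(np.mean(wf1s)),
    }
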