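"""Model/Results facade over the pipeline, in the statsmodels idiom.

``HazardClassifier`` binds data (cube manifests or synthetic generation) to
a network configuration; ``fit`` trains the modified 3D-UNet and returns a
``HazardClassifierResults`` carrying the trained network, the optimization
history, the held-out evaluation report and a ``summary()`` table.

    >>> model = HazardClassifier.from_synthetic(n_train=60, n_val=20, n_test=20)
    >>> res = model.fit(Hyperparameters(epochs=4, seed=0))
    >>> print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import synthetic as syn
from .evaluation import EvaluationReport
from .network import HazardNet, NetworkConfig, build_network, predict as net_predict
from .training import (Hyperparameters, LoadedDataset, PRESETS, SampleRecord,
                       cross_validate, evaluate_network, load_manifest,
                       load_records, load_synthetic, stratified_split, train)

__all__ = ["HazardClassifier", "HazardClassifierResults",
           "save_checkpoint", "load_checkpoint"]


def _resolve_hyper(hyper) -> Hyperparameters:
    if hyper is None:
        return Hyperparameters()
    if isinstance(hyper, str):
        try:
            return PRESETS[hyper]
        except KeyError:
            raise ValueError(
                f"unknown preset {hyper!r}; available: {sorted(PRESETS)}"
            ) from None
    return hyper


class HazardClassifier:
    """Hazard classification from volumetric electron densities.

    Parameters
    ----------
    train_data, val_data, test_data
        ``LoadedDataset`` instances (see the ``from_*`` constructors).
    network_config
        Architecture settings; defaults to :class:`NetworkConfig`.
    """

    def __init__(
        self,
        train_data: LoadedDataset,
        val_data: LoadedDataset,
        test_data: Optional[LoadedDataset] = None,
        network_config: Optional[NetworkConfig] = None,
    ):
        self.train_data = train_data
        self.val_data = val_data
        self.test_data = test_data
        shape = tuple(train_data.inputs.shape[2:])
        channels = train_data.inputs.shape[1]
        self.config = network_config or NetworkConfig(
            in_shape=shape, two_channel_input=(channels == 2)
        )

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_manifest(
        cls,
        path,
        ratios: Tuple[float, float, float] = (0.7, 0.2, 0.1),
        seed: int = 0,
        network_config: Optional[NetworkConfig] = None,
        percentiles: Tuple[float, float] = (10.0, 90.0),
        normalize="max",
    ) -> "HazardClassifier":
        """Split a cube manifest into stratified train/val/test and load it."""
        records = load_manifest(path)
        tr, va, te = stratified_split(records, ratios, seed=seed)
        cfg = network_config or NetworkConfig()
        kw = dict(in_shape=cfg.in_shape, percentiles=percentiles,
                  two_channel=cfg.two_channel_input, normalize=normalize)
        return cls(load_records(tr, **kw), load_records(va, **kw),
                   load_records(te, **kw) if te else None, cfg)

    @classmethod
    def from_synthetic(
        cls,
        config: Optional[syn.SyntheticConfig] = None,
        n_train: int = 600,
        n_val: int = 150,
        n_test: int = 150,
        seed: int = 0,
        network_config: Optional[NetworkConfig] = None,
        in_shape: Optional[Tuple[int, int, int]] = None,
        percentiles: Tuple[float, float] = (10.0, 90.0),
        normalize="max",
    ) -> "HazardClassifier":
        """Generate a planted-signal synthetic study in memory.

        Sample seeds are consecutive offsets from ``seed`` so the three
        parts never overlap.
        """
        config = config or syn.SyntheticConfig()
        if network_config is None and in_shape is not None:
            network_config = NetworkConfig(in_shape=tuple(in_shape))
        shape = network_config.in_shape if network_config else None
        kw = dict(percentiles=percentiles, in_shape=shape, normalize=normalize,
                  two_channel=bool(network_config and network_config.two_channel_input))
        tr = load_synthetic(config, n_train, seed=seed, **kw)
        va = load_synthetic(config, n_val, seed=seed + n_train, **kw)
        te = load_synthetic(config, n_test, seed=seed + n_train + n_val, **kw)
        return cls(tr, va, te, network_config)

    # -- estimation -------------------------------------------------------
    def fit(self, hyper: Hyperparameters | str | None = None,
            seed: Optional[int] = None) -> "HazardClassifierResults":
        """Train the network; evaluate on the test part when present."""
        hyper = _resolve_hyper(hyper)
        if seed is not None:
            from dataclasses import replace
            hyper = replace(hyper, seed=seed)
        network = build_network(self.config, seed=hyper.seed)
        network, history = train(network, self.train_data, self.val_data, hyper)
        eval_data = self.test_data if self.test_data is not None else self.val_data
        report = evaluate_network(network, eval_data, batch_size=hyper.batch_size)
        return HazardClassifierResults(self, network, history, hyper, report)

    def cross_validate(self, hyper: Hyperparameters | str | None = None,
                       k: int = 5, seed: int = 0) -> dict:
        """Stratified k-fold CV over the pooled train+val(+test) data."""
        hyper = _resolve_hyper(hyper)
        parts = [self.train_data, self.val_data] + (
            [self.test_data] if self.test_data is not None else []
        )
        pooled = LoadedDataset(
            np.concatenate([p.inputs for p in parts]),
            np.concatenate([p.masks for p in parts]),
            np.concatenate([p.labels for p in parts]),
            sum((p.ids for p in parts), []),
        )
        return cross_validate(pooled, hyper, self.config, k=k, seed=seed)


class HazardClassifierResults:
    """Fitted-model container: trained network, history, evaluation."""

    def __init__(self, model: HazardClassifier, network: HazardNet,
                 history: pd.DataFrame, hyper: Hyperparameters,
                 report: EvaluationReport):
        self.model = model
        self.network = network
        self.history = history
        self.hyper = hyper
        self.report = report

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    def predict(self, inputs) -> tuple[np.ndarray, np.ndarray]:
        """(ternary mask batch, binary label batch) for a density batch."""
        if isinstance(inputs, LoadedDataset):
            inputs = inputs.inputs
        return net_predict(self.network, inputs)

    def evaluate(self, data: LoadedDataset | Sequence[SampleRecord]) -> EvaluationReport:
        return evaluate_network(self.network, data, batch_size=self.hyper.batch_size)

    def summary(self) -> str:
        cfg = self.model.config
        n_par = self.network.n_parameters()
        lines = [
            "          Hazard classification — modified 3D-UNet",
            "=" * 62,
            f"{'Train samples:':<24}{len(self.model.train_data):>8}"
            f"{'   Epochs run:':<20}{len(self.history):>8}",
            f"{'Validation samples:':<24}{len(self.model.val_data):>8}"
            f"{'   Batch size:':<20}{self.hyper.batch_size:>8}",
            f"{'Test samples:':<24}"
            f"{len(self.model.test_data) if self.model.test_data is not None else 0:>8}"
            f"{'   Learning rate:':<20}{self.hyper.learning_rate:>8.2e}",
            f"{'Input grid:':<24}{str(cfg.in_shape):>8}"
            f"{'   Parameters:':<20}{n_par:>8}",
            "-" * 62,
        ]
        if len(self.history):
            last = self.history.iloc[-1]
            best = self.history["val_acc"].max()
            lines += [
                f"{'Final train loss:':<24}{last['train_total']:>8.4f}"
                f"{'   Final val loss:':<20}{last['val_total']:>8.4f}",
                f"{'Best val accuracy:':<24}{best:>8.4f}",
                "-" * 62,
            ]
        lines.append(self.report.text_table())
        return "\n".join(lines)

    def plot_history(self, path=None):
        """Loss and accuracy curves; returns the matplotlib figure."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        h = self.history
        axes[0].plot(h["epoch"], h["train_total"], label="train")
        axes[0].plot(h["epoch"], h["val_total"], label="validation")
        axes[0].set_xlabel("epoch"); axes[0].set_ylabel("loss (CE + gen. dice)")
        axes[0].legend()
        axes[1].plot(h["epoch"], h["train_acc"], label="train")
        axes[1].plot(h["epoch"], h["val_acc"], label="validation")
        axes[1].set_xlabel("epoch"); axes[1].set_ylabel("accuracy")
        axes[1].legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
        return fig

    def save(self, path) -> Path:
        return save_checkpoint(self.network, path)


def save_checkpoint(network: HazardNet, path) -> Path:
    """Persist parameters + buffers with the architecture config embedded."""
    path = Path(path)
    state = network.state_dict()
    cfg = asdict(network.config)
    cfg["modification_order"] = list(cfg["modification_order"])
    np.savez(path, __config__=json.dumps(cfg), **state)
    return path if path.suffix == ".npz" else Path(str(path) + ".npz")


def load_checkpoint(path) -> HazardNet:
    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["__config__"]))
        cfg_dict["in_shape"] = tuple(cfg_dict["in_shape"])
        cfg_dict["modification_order"] = tuple(cfg_dict["modification_order"])
        config = NetworkConfig(**cfg_dict)
        network = build_network(config, seed=0)
        state = {k: data[k] for k in data.files if k != "__config__"}
    network.load_state_dict(state)
    return network
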