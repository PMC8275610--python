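"""Transfer of an activity-recognition model to the disease task.

Four regimes are supported:

* ``end_to_end`` — no source model; a fresh network is trained on the target
  (disease) task only.
* ``direct`` — the trained source (HAR) body is kept frozen in its entirety;
  only the final dense layer is replaced by a disease head and retrained.
* ``fixed`` — the convolutional blocks act as a fixed feature extractor
  (frozen); all dense layers are retrained.
* ``fine_tune`` — the whole network is initialised from the source model
  (only the head is replaced) and every layer is retrained at a reduced
  learning rate (source lr x ``lr_scale``, default 0.1); the frozen set is
  configurable for partial freezing.

Freezing is exact: frozen parameters are bit-identical before and after
target training (the optimiser never touches them).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .model import (Conv1D, Dense, ModelGraph, TrainConfig, train)
from .preprocessing import EpochDataset

__all__ = ["TransferPlan", "transfer_model", "run_transfer_experiment",
           "REGIMES"]

REGIMES = ("end_to_end", "direct", "fixed", "fine_tune")


@dataclass(frozen=True)
class TransferPlan:
    """How much of the source network to freeze when retargeting it."""

    regime: str = "fine_tune"
    frozen_layers: frozenset[int] | None = None   # None -> derived from regime
    lr_scale: float = 0.1                         # fine-tune lr relative to source

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")


def _layer_indices(model: ModelGraph, kind) -> list[int]:
    return [i for i, l in enumerate(model.layers) if isinstance(l, kind)]


def _frozen_for(plan: TransferPlan, model: ModelGraph) -> set[int]:
    if plan.frozen_layers is not None:
        for i in plan.frozen_layers:
            if i < 0 or i >= len(model.layers) or not model.layers[i].params():
                raise ValueError(f"cannot freeze layer {i}: not a parametric layer")
        return set(plan.frozen_layers)
    conv = set(_layer_indices(model, Conv1D))
    dense = _layer_indices(model, Dense)
    head = dense[-1]
    if plan.regime == "direct":
        return (conv | set(dense)) - {head}
    if plan.regime == "fixed":
        return conv
    return set()  # fine_tune (warm start, nothing frozen) and end_to_end


def transfer_model(source_model: ModelGraph, target_labels: tuple[str, ...],
                   plan: TransferPlan, rng_seed: int = 0) -> ModelGraph:
    """Replace the source head with a fresh target head and apply freezing.

    The final dense layer is re-initialised with ``len(target_labels)`` units;
    every other parameter is copied verbatim from the source model. Layers in
    the plan's frozen set are flagged non-trainable.
    """
    target_labels = tuple(target_labels)
    overlap = set(target_labels) & set(source_model.label_space)
    if overlap:
        raise ValueError(f"target labels collide with source labels: {sorted(overlap)}")
    model = source_model.copy()
    dense_idx = _layer_indices(model, Dense)
    if not dense_idx:
        raise ValueError("source model has no dense head to replace")
    head_i = dense_idx[-1]
    old: Dense = model.layers[head_i]
    rng = np.random.default_rng(rng_seed)
    model.layers[head_i] = Dense(old.w.shape[0], len(target_labels), rng,
                                 old.use_bias)
    model.label_space = target_labels
    model.set_frozen(_frozen_for(plan, model))
    return model


def run_transfer_experiment(source_dataset: EpochDataset | None,
                            target_train: EpochDataset,
                            target_test: EpochDataset,
                            plan: TransferPlan,
                            cfg: TrainConfig = TrainConfig(),
                            source_cfg: TrainConfig | None = None,
                            arch=None,
                            source_model: ModelGraph | None = None,
                            ) -> tuple[ModelGraph, dict]:
    """Train under one regime and evaluate on held-out target subjects.

    For transfer regimes the source model is trained on the HAR dataset first
    (or supplied pre-trained via ``source_model``); ``end_to_end`` ignores the
    source entirely. Returns the trained target model and a metrics dict from
    :func:`gaitscope.evaluation.evaluate_split`.
    """
    from .evaluation import evaluate_split
    from .model import DEFAULT_ARCH, build_dcnn

    arch = DEFAULT_ARCH if arch is None else arch
    if target_train.X.shape[1:] != target_test.X.shape[1:]:
        raise ValueError("target train/test epoch shapes differ")
    target_labels = target_train.label_space

    if plan.regime == "end_to_end":
        model = build_dcnn(target_labels, arch=arch, rng_seed=cfg.rng_seed)
        tcfg = cfg
    else:
        if source_model is None:
            if source_dataset is None:
                raise ValueError(f"{plan.regime} transfer requires a source dataset or model")
            if source_dataset.X.shape[1:] != target_train.X.shape[1:]:
                raise ValueError("source/target epoch shapes differ")
            scfg = source_cfg if source_cfg is not None else cfg
            source_model = build_dcnn(source_dataset.label_space, arch=arch,
                                      rng_seed=scfg.rng_seed)
            source_model, _ = train(source_model, source_dataset, scfg)
        model = transfer_model(source_model, target_labels, plan,
                               rng_seed=cfg.rng_seed)
        lr = cfg.learning_rate * (plan.lr_scale if plan.regime == "fine_tune" else 1.0)
        tcfg = dc_replace(cfg, learning_rate=lr)

    model, history = train(model, target_train, tcfg)
    report = evaluate_split(model, target_test)
    report["history"] = history
    return model, report
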