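"""Patient-level splitting and the regularized training loop.

Splits are always by patient: one patient is held out entirely as the test
set and the remaining patients are partitioned into k cross-validation folds
(each patient validates in exactly one fold).  Training minimizes the
combined main + lambda*aux loss with mini-batch SGD (momentum, L2 weight
decay), reduces the learning rate when the validation loss plateaus, stops
early when it fails to improve, and returns the best-validation checkpoint.

Augmentation (random flips / 90-degree rotation) is applied to training
batches only; patches are standardized with channel statistics computed once
per fold from that fold's training patches.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn
from .core_io import ValidationError
from .modeling import ExpressionModel, LossSpec, build_model, combined_loss, predict
from .preprocessing import PreprocessResult, augment_patch, standardize_patch

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "TrainConfig",
    "FoldData",
    "make_splits",
    "train_fold",
    "run_experiment",
    "ExperimentResult",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class SplitPlan:
    """Held-out test patient plus k (train, validation) patient partitions."""

    test_patient: str
    cv_folds: list[tuple[list[str], list[str]]]

    def __post_init__(self) -> None:
        seen_val: list[str] = []
        for train, val in self.cv_folds:
            if self.test_patient in train or self.test_patient in val:
                raise ValidationError("test patient leaked into a fold")
            if set(train) & set(val):
                raise ValidationError("train/val patient overlap within a fold")
            seen_val.extend(val)
        if len(seen_val) != len(set(seen_val)):
            raise ValidationError("a patient validates in more than one fold")


@dataclass
class TrainConfig:
    """Optimization settings (defaults follow the published setup: batch 32,
    up to 200 epochs, SGD at lr 0.001 with momentum and weight decay)."""

    batch_size: int = 32
    max_epochs: int = 200
    lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-4
    early_stopping_patience: int = 20
    scheduler_factor: float = 0.1
    scheduler_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("batch_size", "max_epochs", "early_stopping_patience"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.lr < 0:
            raise ValidationError("lr must be >= 0")


@dataclass
class FoldData:
    """Raw uint8 patches and log-expression targets for one fold."""

    train_patches: np.ndarray
    train_main: np.ndarray
    train_aux: np.ndarray | None
    val_patches: np.ndarray
    val_main: np.ndarray
    val_aux: np.ndarray | None


def make_splits(
    patient_ids: list[str],
    test_patient: str,
    n_folds: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Partition patients into a test patient and k cross-validation folds.

    Fold sizes differ by at most one (e.g. 22 patients over 5 folds give
    validation folds of sizes 5, 5, 4, 4, 4); deterministic for a seed.
    """
    unique = sorted(set(map(str, patient_ids)))
    if test_patient not in unique:
        raise ValidationError(f"unknown test patient '{test_patient}'")
    rest = [p for p in unique if p != test_patient]
    if n_folds > len(rest):
        raise ValidationError(
            f"n_folds={n_folds} exceeds the {len(rest)} non-test patients"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(rest))
    chunks = [list(c) for c in np.array_split(order, n_folds)]
    folds = [
        (sorted(set(rest) - set(chunk)), sorted(chunk)) for chunk in chunks
    ]
    return SplitPlan(test_patient=test_patient, cv_folds=folds)


def _loader_loss(
    model: ExpressionModel,
    patches: np.ndarray,
    main: np.ndarray,
    aux: np.ndarray | None,
    spec: LossSpec,
    stats: tuple[np.ndarray, np.ndarray],
    batch_size: int,
) -> float:
    """Evaluation-mode combined loss over a whole loader."""
    total, n = 0.0, 0
    for start in range(0, len(patches), batch_size):
        sl = slice(start, start + batch_size)
        x = standardize_patch(patches[sl], *stats)
        pm, pa = model.forward(x, train=False)
        loss, _, _, _ = combined_loss(
            pm, main[sl], pa, None if aux is None else aux[sl], spec
        )
        n_batch = len(x)
        total += loss * n_batch
        n += n_batch
    return total / max(n, 1)


def train_fold(
    model: ExpressionModel,
    fold_data: FoldData,
    train_config: TrainConfig,
    loss_spec: LossSpec,
) -> tuple[ExpressionModel, dict]:
    """Train one fold and return the best-validation-loss model and history.

    The returned model carries the checkpoint of the epoch with the lowest
    validation loss, never a worse one.
    """
    rng = np.random.default_rng(train_config.seed)
    # head init policy: weights zero, biases at the per-gene training means.
    # Regression targets have large non-zero means; absorbing them keeps the
    # early gradients small under large lambda, and a zero weight matrix means
    # a head predicting an uninformative gene injects no gradient noise into
    # the shared features until its own gradient says otherwise.
    model.main_head.params["W"][...] = 0.0
    model.main_head.params["b"][...] = fold_data.train_main.mean(axis=0)
    if model.aux_enabled and fold_data.train_aux is not None:
        model.aux_head.params["W"][...] = 0.0
        model.aux_head.params["b"][...] = fold_data.train_aux.mean(axis=0)
    params = model.parameters()
    opt = _nn.SGD(
        params,
        lr=train_config.lr,
        momentum=train_config.momentum,
        weight_decay=train_config.weight_decay,
    )
    scheduler = _nn.ReduceLROnPlateau(
        opt,
        factor=train_config.scheduler_factor,
        patience=train_config.scheduler_patience,
    )

    tr = fold_data.train_patches.astype(np.float32)
    channel_means = tr.mean(axis=(0, 2, 3))
    channel_stds = np.maximum(tr.std(axis=(0, 2, 3)), 1e-6)
    stats = (channel_means, channel_stds)
    del tr

    best_val = np.inf
    best_state = model.get_state()
    bad_epochs = 0
    history: list[dict] = []
    n_train = len(fold_data.train_patches)

    for epoch in range(train_config.max_epochs):
        order = rng.permutation(n_train)
        train_loss_sum, n_seen = 0.0, 0
        for bstart in range(0, n_train, train_config.batch_size):
            idx = order[bstart : bstart + train_config.batch_size]
            batch = np.stack(
                [augment_patch(fold_data.train_patches[i], rng) for i in idx]
            )
            x = standardize_patch(batch, *stats)
            opt.zero_grad()
            pm, pa = model.forward(x, train=True)
            loss, _, gm, ga = combined_loss(
                pm,
                fold_data.train_main[idx],
                pa,
                None if fold_data.train_aux is None else fold_data.train_aux[idx],
                loss_spec,
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch "
                    f"{bstart // train_config.batch_size}"
                )
            model.backward(gm, ga)
            opt.step()
            train_loss_sum += loss * len(idx)
            n_seen += len(idx)

        val_loss = _loader_loss(
            model,
            fold_data.val_patches,
            fold_data.val_main,
            fold_data.val_aux,
            loss_spec,
            stats,
            train_config.batch_size,
        )
        history.append(
            {
                "epoch": epoch,
                "train_loss": train_loss_sum / max(n_seen, 1),
                "val_loss": val_loss,
                "lr": opt.lr,
            }
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.get_state()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= train_config.early_stopping_patience:
                logger.info("early stop at epoch %d (best val %.5f)", epoch, best_val)
                break
        scheduler.step(val_loss)

    model.set_state(best_state)
    return model, {
        "history": history,
        "best_val_loss": float(best_val),
        "channel_means": channel_means,
        "channel_stds": channel_stds,
        "n_epochs": len(history),
    }


@dataclass
class ExperimentResult:
    """Per-fold models plus their predictions on the held-out patient."""

    split_plan: SplitPlan
    models: list[ExpressionModel]
    fold_info: list[dict]
    predictions: pd.DataFrame  # (unit, spot) MultiIndex x main genes
    aux_predictions: pd.DataFrame | None
    targets: pd.DataFrame  # spot x main genes (log expression)
    aux_targets: pd.DataFrame | None
    main_genes: list[str] = field(default_factory=list)


def run_experiment(
    pre: PreprocessResult,
    test_patient: str,
    backbone: str = "tiny_cnn",
    n_folds: int = 5,
    train_config: TrainConfig | None = None,
    loss_spec: LossSpec | None = None,
    aux_enabled: bool = True,
    seed: int = 0,
) -> ExperimentResult:
    """Train all folds and predict every retained spot of the test patient."""
    train_config = train_config or TrainConfig(seed=seed)
    loss_spec = loss_spec or LossSpec()

    patients = np.asarray(pre.bundle.patient, dtype=str)
    spot_uids = [
        f"{p}|{s}|{sp}"
        for p, s, sp in zip(patients, pre.bundle.section_ids, pre.bundle.spot_ids)
    ]
    main_genes = pre.selection.main_genes
    aux_genes = pre.selection.aux_genes
    main_t = pre.log_counts[main_genes].to_numpy(dtype=np.float32)
    aux_t = (
        pre.log_counts[aux_genes].to_numpy(dtype=np.float32) if aux_genes else None
    )

    plan = make_splits(list(np.unique(patients)), test_patient, n_folds, seed)
    test_mask = patients == test_patient
    test_idx = np.where(test_mask)[0]
    if not len(test_idx):
        raise ValidationError(f"no retained spots for test patient {test_patient}")

    patch_size = pre.patches.patches.shape[-1]
    models, fold_info, pred_frames, aux_frames = [], [], [], []
    test_uids = [spot_uids[i] for i in test_idx]

    for fold_i, (train_p, val_p) in enumerate(plan.cv_folds):
        train_mask = np.isin(patients, train_p)
        val_mask = np.isin(patients, val_p)
        # split hygiene: the held-out patient must appear in no loader
        assert not (train_mask & test_mask).any() and not (val_mask & test_mask).any()

        fold = FoldData(
            train_patches=pre.patches.patches[train_mask],
            train_main=main_t[train_mask],
            train_aux=None if aux_t is None else aux_t[train_mask],
            val_patches=pre.patches.patches[val_mask],
            val_main=main_t[val_mask],
            val_aux=None if aux_t is None else aux_t[val_mask],
        )
        model = build_model(
            backbone,
            n_main=len(main_genes),
            n_aux=len(aux_genes),
            aux_enabled=aux_enabled,
            input_size=patch_size,
            seed=seed * 100 + fold_i,
        )
        fold_cfg = dataclasses.replace(
            train_config, seed=train_config.seed * 100 + fold_i
        )
        model, info = train_fold(model, fold, fold_cfg, loss_spec)
        models.append(model)
        info["fold"] = fold_i
        info["val_patients"] = val_p
        fold_info.append(info)

        stats = (info["channel_means"], info["channel_stds"])
        x_test = standardize_patch(pre.patches.patches[test_idx], *stats)
        pm, pa = predict(model, x_test)
        pred_frames.append(
            pd.DataFrame(
                pm,
                index=pd.MultiIndex.from_product(
                    [[f"fold{fold_i}"], test_uids], names=["unit", "spot"]
                ),
                columns=main_genes,
            )
        )
        if pa is not None:
            aux_frames.append(
                pd.DataFrame(
                    pa,
                    index=pred_frames[-1].index,
                    columns=aux_genes,
                )
            )

    targets = pd.DataFrame(
        main_t[test_idx], index=pd.Index(test_uids, name="spot"), columns=main_genes
    )
    aux_targets = (
        pd.DataFrame(
            aux_t[test_idx], index=pd.Index(test_uids, name="spot"), columns=aux_genes
        )
        if aux_t is not None
        else None
    )
    return ExperimentResult(
        split_plan=plan,
        models=models,
        fold_info=fold_info,
        predictions=pd.concat(pred_frames),
        aux_predictions=pd.concat(aux_frames) if aux_frames else None,
        targets=targets,
        aux_targets=aux_targets,
        main_genes=list(main_genes),
    )


def save_checkpoint(model: ExpressionModel, path: str | Path, extra: dict | None = None) -> None:
    """Persist model weights as an ``.npz`` plus a JSON metadata sidecar."""
    path = Path(path)
    state = model.get_state()
    np.savez(path, **{f"param_{i}": p for i, p in enumerate(state)})
    meta = {
        "backbone": model.backbone_name,
        "n_main": model.n_main,
        "n_aux": model.n_aux,
        "aux_enabled": model.aux_enabled,
        "input_size": model.input_size,
        **(extra or {}),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def load_checkpoint(path: str | Path) -> tuple[ExpressionModel, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    model = build_model(
        meta["backbone"],
        n_main=meta["n_main"],
        n_aux=meta["n_aux"],
        aux_enabled=meta["aux_enabled"],
        input_size=meta["input_size"],
    )
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        state = [data[f"param_{i}"] for i in range(len(data.files))]
    model.set_state(state)
    return model, meta
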