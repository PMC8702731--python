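"""Training loop, cross-validation and ablation harness.

Training follows the study protocol: Adam (initial learning rate 0.001,
weight decay 0.0005) with a poly learning-rate schedule
``lr = base * (1 - iter / max_iter) ** power`` (power 0.9), a hard cap of
``max_iterations`` optimizer steps, flip/affine augmentation, per-volume
min-max normalization after augmentation, and best-checkpoint selection by
mean foreground DSC on the held-out fold of the cross-validation round.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .losses import LossConfig, combined_loss
from .net import CascadeNet, NetConfig, build_model
from .nn import Adam, Tensor
from .seg_metrics import MetricsReport, evaluate_case, reports_to_table
from .volume import ImageVolume, LabelVolume

__all__ = [
    "TrainConfig", "TrainResult", "poly_lr", "kfold_split", "train",
    "predict_volume", "cross_validate", "run_ablation",
    "save_checkpoint", "load_checkpoint", "ABLATION_ARMS",
]

#: The three ablation arms: plain residual blocks, multi-scale Res2 blocks,
#: and Res2 blocks plus the refinement stage (the full model).
ABLATION_ARMS = ("resblock", "res2block", "res2block+refine")


@dataclass
class TrainConfig:
    base_lr: float = 0.001
    weight_decay: float = 0.0005
    poly_power: float = 0.9
    max_iterations: int = 1000
    iteration_unit: str = "step"      # {"step", "epoch"}
    batch_size: int = 2
    folds: int = 5
    seed: int = 0
    augment: bool = True
    eval_every: int = 25
    early_stop_patience: int | None = None  # evals without val improvement
    target_train_dsc: float | None = None   # optional early exit on train DSC
    target_class: int | None = None         # restrict the target to one class

    def __post_init__(self) -> None:
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.iteration_unit not in ("step", "epoch"):
            raise ValueError("iteration_unit must be 'step' or 'epoch'")


@dataclass
class TrainResult:
    model: CascadeNet
    best_state: dict
    best_iteration: int
    best_val_dsc: float
    train_log: list[dict] = field(default_factory=list)
    val_log: list[dict] = field(default_factory=list)

    def restore_best(self) -> CascadeNet:
        self.model.load_state_dict(self.best_state)
        return self.model


def poly_lr(iteration: int, cfg: TrainConfig) -> float:
    """Poly schedule: base_lr * (1 - iteration / max_iterations) ** power."""
    if not 0 <= iteration <= cfg.max_iterations:
        raise ValueError(
            f"iteration {iteration} outside [0, {cfg.max_iterations}]"
        )
    return cfg.base_lr * (1.0 - iteration / cfg.max_iterations) ** cfg.poly_power


def kfold_split(case_ids: list, k: int = 5, seed: int = 0) -> list[list]:
    """Disjoint, exhaustive, near-equal folds; deterministic given seed."""
    case_ids = list(case_ids)
    if k > len(case_ids):
        raise ValueError(f"k={k} exceeds number of cases ({len(case_ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(case_ids))
    return [[case_ids[i] for i in part] for part in np.array_split(order, k)]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _normalized_input(img: ImageVolume) -> np.ndarray:
    return vio.normalize01(img).values


def _mean_foreground_dsc(model: CascadeNet, cases, classes=(1, 2, 3)) -> float:
    from .seg_metrics import dsc

    scores = []
    for img, lab in cases:
        pred = model.predict_labels(_normalized_input(img))
        for cls in classes:
            scores.append(dsc(pred == cls, lab.values == cls))
    return float(np.mean(scores))


def train(
    train_cases: list[tuple[ImageVolume, LabelVolume]],
    val_cases: list[tuple[ImageVolume, LabelVolume]] | None,
    cfg: TrainConfig | None = None,
    net_cfg: NetConfig | None = None,
    loss_cfg: LossConfig | None = None,
    model: CascadeNet | None = None,
    verbose: bool = False,
) -> TrainResult:
    """Optimize the cascade on already-resampled/cropped volume pairs.

    Augmentation (when enabled) and per-volume normalization are applied per
    sampled volume each step; the validation metric is the mean foreground
    DSC over ``val_cases`` (falling back to the training cases when no
    validation split is given, i.e. pure overfitting runs). A NaN loss
    aborts with a diagnostic snapshot.
    """
    if not train_cases:
        raise ValueError("train_cases must be nonempty")
    cfg = cfg or TrainConfig()
    net_cfg = net_cfg or NetConfig()
    loss_cfg = loss_cfg or LossConfig()
    if model is None:
        model = build_model(net_cfg, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)

    max_steps = cfg.max_iterations
    if cfg.iteration_unit == "epoch":
        steps_per_epoch = max(1, len(train_cases) // cfg.batch_size)
        max_steps = cfg.max_iterations * steps_per_epoch
    sched_cfg = TrainConfig(**{**asdict(cfg), "max_iterations": max_steps,
                               "iteration_unit": "step"})

    opt = Adam(model.parameters(), lr=cfg.base_lr, weight_decay=cfg.weight_decay)
    eval_cases = val_cases if val_cases else train_cases

    result = TrainResult(model=model, best_state=model.state_dict(),
                         best_iteration=0, best_val_dsc=-1.0)
    stale = 0
    t0 = time.time()
    for step in range(max_steps):
        opt.lr = poly_lr(step, sched_cfg)
        model.train()
        batch_losses = []
        opt.zero_grad()
        loss_acc = None
        for _ in range(cfg.batch_size):
            idx = int(rng.integers(0, len(train_cases)))
            img, lab = train_cases[idx]
            if cfg.augment:
                img, lab = vio.augment(img, lab, seed=int(rng.integers(0, 2**31 - 1)))
            x = Tensor(_normalized_input(img)[None, ..., None].astype(np.float32))
            coarse, refined = model(x)
            loss = combined_loss(coarse, refined, lab.values[None], loss_cfg)
            loss_acc = loss if loss_acc is None else loss_acc + loss
            batch_losses.append(loss.item())
        loss_mean = loss_acc * (1.0 / cfg.batch_size)
        if not np.isfinite(loss_mean.item()):
            raise RuntimeError(
                "NaN/inf training loss at iteration "
                f"{step}: lr={opt.lr:.3g}, recent losses="
                f"{[round(l['loss'], 4) for l in result.train_log[-5:]]}"
            )
        loss_mean.backward()
        opt.step()
        result.train_log.append({"iteration": step, "lr": opt.lr,
                                 "loss": float(loss_mean.item())})

        last = step == max_steps - 1
        if (step + 1) % cfg.eval_every == 0 or last:
            val_dsc = _mean_foreground_dsc(model, eval_cases)
            result.val_log.append({"iteration": step, "mean_dsc": val_dsc})
            if verbose:
                print(f"iter {step + 1}/{max_steps} loss={loss_mean.item():.4f} "
                      f"val_dsc={val_dsc:.4f} ({time.time() - t0:.0f}s)")
            if val_dsc > result.best_val_dsc:
                result.best_val_dsc = val_dsc
                result.best_iteration = step
                result.best_state = model.state_dict()
                stale = 0
            else:
                stale += 1
            if cfg.target_train_dsc is not None:
                classes = (cfg.target_class,) if cfg.target_class is not None else (1, 2, 3)
                train_dsc = _mean_foreground_dsc(model, train_cases, classes=classes)
                if train_dsc >= cfg.target_train_dsc:
                    # the stopping criterion selects the current model
                    result.best_state = model.state_dict()
                    result.best_iteration = step
                    result.best_val_dsc = val_dsc
                    break
            if cfg.early_stop_patience is not None and stale >= cfg.early_stop_patience:
                break
    model.load_state_dict(result.best_state)
    return result


def predict_volume(model: CascadeNet, img: ImageVolume) -> LabelVolume:
    """Normalize, run the cascade, argmax to a hard label volume."""
    labels = model.predict_labels(_normalized_input(img))
    return LabelVolume(labels, spacing_mm=img.spacing_mm, origin_mm=img.origin_mm)


# ---------------------------------------------------------------------------
# cross-validation & ablation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_reports: list[list[MetricsReport]]
    fold_assignments: list[list[int]]

    def table(self) -> pd.DataFrame:
        return reports_to_table([r for fold in self.fold_reports for r in fold])

    def mean_per_class(self) -> pd.DataFrame:
        tab = self.table()
        return tab.groupby("class")[["dsc", "hd", "asd"]].mean()


def cross_validate(
    cases: list[tuple[ImageVolume, LabelVolume]],
    cfg: TrainConfig | None = None,
    net_cfg: NetConfig | None = None,
    loss_cfg: LossConfig | None = None,
    verbose: bool = False,
) -> CVResult:
    """k-fold cross-validation: train on k-1 folds, evaluate the held-out fold.

    Case-id disjointness between train and held-out partitions is asserted;
    best-model selection within a round uses the held-out fold.
    """
    cfg = cfg or TrainConfig()
    folds = kfold_split(list(range(len(cases))), k=cfg.folds, seed=cfg.seed)
    fold_reports: list[list[MetricsReport]] = []
    for fi, held_out in enumerate(folds):
        train_ids = [i for f in folds for i in f if f is not held_out]
        assert not set(train_ids) & set(held_out), "train/test fold leak"
        train_cs = [cases[i] for i in train_ids]
        val_cs = [cases[i] for i in held_out]
        res = train(train_cs, val_cs, cfg=cfg, net_cfg=net_cfg,
                    loss_cfg=loss_cfg, verbose=verbose)
        model = res.restore_best()
        reports = []
        for i in held_out:
            img, lab = cases[i]
            pred = predict_volume(model, img)
            reports.append(evaluate_case(pred, lab, case_id=f"fold{fi}_case{i}"))
        fold_reports.append(reports)
    return CVResult(fold_reports=fold_reports, fold_assignments=folds)


def _arm_net_cfg(arm: str, base: NetConfig) -> NetConfig:
    if arm not in ABLATION_ARMS:
        raise ValueError(f"unknown ablation arm {arm!r}; expected one of {ABLATION_ARMS}")
    block = "resblock" if arm == "resblock" else "res2block"
    refine = arm.endswith("+refine")
    return NetConfig(**{**base.__dict__, "block": block, "refine": refine})


def run_ablation(
    cases: list[tuple[ImageVolume, LabelVolume]],
    arms: tuple[str, ...] = ABLATION_ARMS,
    cfg: TrainConfig | None = None,
    net_cfg: NetConfig | None = None,
    loss_cfg: LossConfig | None = None,
    verbose: bool = False,
) -> pd.DataFrame:
    """Train each arm under identical folds/seeds; return a comparative table.

    Rows are arms; columns are per-class mean DSC/HD/ASD over the held-out
    folds plus deltas of mean DSC relative to the first arm.
    """
    if len(arms) < 2:
        raise ValueError("an ablation needs at least 2 arms")
    cfg = cfg or TrainConfig()
    base_net = net_cfg or NetConfig()
    rows = {}
    for arm in arms:
        cv = cross_validate(cases, cfg=cfg, net_cfg=_arm_net_cfg(arm, base_net),
                            loss_cfg=loss_cfg, verbose=verbose)
        per_class = cv.mean_per_class()
        row = {}
        for code in per_class.index:
            for metric in ("dsc", "hd", "asd"):
                row[f"{metric}_{code}"] = per_class.loc[code, metric]
        rows[arm] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    ref = table.iloc[0]
    for col in [c for c in table.columns if c.startswith("dsc_")]:
        table[f"delta_{col}"] = table[col] - ref[col]
    table.index.name = "arm"
    return table


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: CascadeNet,
                    train_cfg: TrainConfig | None = None,
                    preprocessing: dict | None = None) -> None:
    """Bundle weights + configs (+ preprocessing fingerprint) into one .npz."""
    path = Path(path)
    meta = {
        "net_cfg": model.cfg.__dict__,
        "train_cfg": asdict(train_cfg) if train_cfg else None,
        "preprocessing": preprocessing or {},
    }
    state = model.state_dict()
    np.savez_compressed(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path: str | Path) -> tuple[CascadeNet, dict]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = build_model(NetConfig(**meta["net_cfg"]))
    model.load_state_dict(state)
    return model, meta
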