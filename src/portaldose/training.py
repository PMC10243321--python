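"""Two-step learning, cross-validation splitting, callbacks, model selection.

Stage 1 trains the bare U-net on normalized portal-image / dose pairs with
Adam and a mean-squared-error loss.  The True Dose Modulation layer is then
computed from the large open calibration square and attached to the network
output, and stage 2 fine-tunes all U-net parameters (the TDM stays frozen)
at a lower learning rate on the same training and validation sets.

Callbacks mirror common practice: reduce-on-plateau learning rate (factor
0.8 after 4 stagnant epochs), early stopping (5 stagnant epochs, strict
improvement), and best-state restoration on the validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GridSpec
from .model import TDMLayer, UNet, UNetSpec, apply_tdm, build_unet, compute_tdm
from .nn import DTYPE, Adam, mse_loss
from .preprocessing import (
    NormalizationFactors,
    compute_norm_factors,
    default_crop_px,
    edge_correct,
    normalize,
)
from .synthetic_beams import REFERENCE_SQUARE_MM, TDM_SQUARE_MM, FieldPair

__all__ = [
    "TrainingConfig",
    "FoldSplit",
    "TrainingHistory",
    "PreparedDataset",
    "TwoStepResult",
    "prepare_dataset",
    "split_folds",
    "reduce_lr_on_plateau",
    "train_stage1",
    "two_step_train",
    "select_model",
]


@dataclass
class TrainingConfig:
    """Optimization settings; defaults follow the two-step recipe."""

    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-6
    lr_stage1: float = 1e-3
    lr_finetune: float = 1e-4
    plateau_factor: float = 0.8
    plateau_patience: int = 4
    early_stop_patience: int = 5
    batch_size: int = 4
    max_epochs_stage1: int = 200
    max_epochs_finetune: int = 200
    gamma_monitor_every: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("Adam betas must lie in (0, 1)")
        if self.lr_stage1 <= 0 or self.lr_finetune <= 0:
            raise ValueError("learning rates must be > 0")
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patiences must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.validation), set(self.test)]
        total = len(self.train) + len(self.validation) + len(self.test)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("train/validation/test sets must be pairwise disjoint")


@dataclass
class TrainingHistory:
    """Per-epoch record of one (possibly two-stage) training run."""

    stage: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    mean_gamma: list[float] = field(default_factory=list)
    passing_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1
    attach_epoch: int | None = None  # epoch index at which the TDM was attached

    def __len__(self) -> int:
        return len(self.val_loss)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self)),
                "stage": self.stage,
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "lr": self.lr,
                "mean_gamma": self.mean_gamma,
                "passing_rate": self.passing_rate,
            }
        )


@dataclass
class PreparedDataset:
    """Edge-corrected, normalized arrays ready for the network (NHWC float32)."""

    X: np.ndarray
    Y: np.ndarray
    cal_mpi_260: np.ndarray  # normalized TDM-beam image, (1, n, n, 1)
    cal_ppd_260: np.ndarray  # normalized TDM-beam dose, (n, n)
    norm: NormalizationFactors
    grid: GridSpec
    crop_px: int


def prepare_dataset(
    pairs: list[FieldPair],
    calibration: dict[float, FieldPair],
    crop_px: int | None = None,
) -> PreparedDataset:
    """Apply edge correction and normalization to a simulated dataset.

    Normalization factors come from the 80 mm square; the edge correction is
    applied to every image and dose, including the TDM calibration pair.
    """
    if REFERENCE_SQUARE_MM not in calibration:
        raise ValueError("calibration set lacks the 80 mm normalization beam")
    if TDM_SQUARE_MM not in calibration:
        raise ValueError("calibration set lacks the 260 mm TDM beam")
    ref = calibration[REFERENCE_SQUARE_MM]
    grid = ref.mpi.grid
    cp = default_crop_px(grid) if crop_px is None else crop_px
    norm = compute_norm_factors(ref.mpi, ref.ppd)

    def prep_mpi(p: FieldPair) -> np.ndarray:
        return normalize(edge_correct(p.mpi.values.astype(np.float64), cp), norm.input_factor)

    def prep_ppd(p: FieldPair) -> np.ndarray:
        return normalize(edge_correct(p.ppd.values, cp), norm.output_factor)

    X = np.stack([prep_mpi(p) for p in pairs])[..., None].astype(DTYPE)
    Y = np.stack([prep_ppd(p) for p in pairs])[..., None].astype(DTYPE)
    tdm_pair = calibration[TDM_SQUARE_MM]
    return PreparedDataset(
        X=X,
        Y=Y,
        cal_mpi_260=prep_mpi(tdm_pair)[None, :, :, None].astype(DTYPE),
        cal_ppd_260=prep_ppd(tdm_pair),
        norm=norm,
        grid=grid,
        crop_px=cp,
    )


# ---------------------------------------------------------------------------
# splitting and schedules


def split_folds(n_samples: int, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """k-fold splits: disjoint near-equal test sets covering all samples,
    the remaining pool split 80/20 into train/validation per fold."""
    if n_samples < k:
        raise ValueError(f"need at least {k} samples, got {n_samples}")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0]))
    perm = rng.permutation(n_samples)
    base, rem = divmod(n_samples, k)
    sizes = [base] * (k - rem) + [base + 1] * rem  # remainder lands on later folds
    folds: list[FoldSplit] = []
    start = 0
    for f in range(k):
        test = perm[start : start + sizes[f]]
        start += sizes[f]
        pool = np.concatenate([perm[: start - sizes[f]], perm[start:]])
        rng_f = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, f + 1]))
        pool = rng_f.permutation(pool)
        n_train = round(0.8 * len(pool))
        folds.append(
            FoldSplit(
                fold_id=f,
                train=np.sort(pool[:n_train]),
                validation=np.sort(pool[n_train:]),
                test=np.sort(test),
            )
        )
    return folds


def reduce_lr_on_plateau(
    val_losses: list[float],
    initial_lr: float,
    factor: float = 0.8,
    patience: int = 4,
) -> float:
    """Replay the plateau rule over a validation-loss history.

    The learning rate is multiplied by ``factor`` each time the loss fails to
    strictly improve for ``patience`` consecutive epochs (the stagnation
    counter resets after each reduction and after each improvement).
    """
    if not len(val_losses):
        raise ValueError("history must be nonempty")
    lr = initial_lr
    best = np.inf
    stagnant = 0
    for loss in val_losses:
        if loss < best:
            best = loss
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= patience:
                lr *= factor
                stagnant = 0
    return lr


# ---------------------------------------------------------------------------
# fitting


def _forward_loss(net: UNet, tdm: TDMLayer | None, X: np.ndarray, Y: np.ndarray) -> float:
    """Validation loss over a set, batched to bound memory."""
    total = 0.0
    for i in range(0, len(X), 8):
        xb, yb = X[i : i + 8], Y[i : i + 8]
        pred = net.forward(xb)
        if tdm is not None:
            pred = apply_tdm(pred, tdm)
        loss, _ = mse_loss(pred, yb)
        total += loss * len(xb)
    return total / len(X)


def _fit(
    net: UNet,
    tdm: TDMLayer | None,
    X: np.ndarray,
    Y: np.ndarray,
    Xval: np.ndarray,
    Yval: np.ndarray,
    cfg: TrainingConfig,
    lr0: float,
    max_epochs: int,
    rng: np.random.Generator,
    history: TrainingHistory,
    stage: int,
    gamma_monitor=None,
) -> None:
    """One training stage with plateau LR, early stopping, best-state restore."""
    opt = Adam(net.params(), lr0, cfg.beta1, cfg.beta2, cfg.epsilon)
    tdm_batch = (
        None if tdm is None else tdm.values.astype(DTYPE)[None, :, :, None]
    )
    best_val = np.inf
    best_state = net.state_dict()
    best_epoch = len(history)
    plateau = 0
    stop = 0
    for epoch in range(max_epochs):
        order = rng.permutation(len(X))
        train_total = 0.0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            pred = net.forward(xb)
            if tdm_batch is not None:
                loss, grad = mse_loss(pred * tdm_batch, yb)
                grad = grad * tdm_batch
            else:
                loss, grad = mse_loss(pred, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at stage {stage}, epoch {epoch}, lr {opt.lr:g}, "
                    f"batch mean {float(xb.mean()):g}, target mean {float(yb.mean()):g}"
                )
            opt.zero_grad()
            net.backward(grad)
            opt.step()
            train_total += loss * len(idx)
        val_loss = _forward_loss(net, tdm, Xval, Yval)

        history.stage.append(stage)
        history.train_loss.append(train_total / len(X))
        history.val_loss.append(val_loss)
        history.lr.append(opt.lr)
        if gamma_monitor is not None and (epoch + 1) % cfg.gamma_monitor_every == 0:
            mg, pr = gamma_monitor(net, tdm)
            history.mean_gamma.append(mg)
            history.passing_rate.append(pr)
        else:
            history.mean_gamma.append(np.nan)
            history.passing_rate.append(np.nan)

        if val_loss < best_val:
            best_val = val_loss
            best_state = net.state_dict()
            best_epoch = len(history) - 1
            plateau = 0
            stop = 0
        else:
            plateau += 1
            stop += 1
            if plateau >= cfg.plateau_patience:
                opt.lr *= cfg.plateau_factor
                plateau = 0
            if stop >= cfg.early_stop_patience:
                break
    net.load_state_dict(best_state)
    history.best_epoch = best_epoch


def train_stage1(
    dataset: PreparedDataset,
    fold: FoldSplit,
    unet: UNet,
    cfg: TrainingConfig,
    gamma_monitor=None,
) -> tuple[UNet, TrainingHistory]:
    """Stage-1 training of the bare U-net (no TDM); restores the best state."""
    history = TrainingHistory()
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.rng_seed & 0x7FFFFFFF, fold.fold_id, 1])
    )
    _fit(
        unet,
        None,
        dataset.X[fold.train],
        dataset.Y[fold.train],
        dataset.X[fold.validation],
        dataset.Y[fold.validation],
        cfg,
        cfg.lr_stage1,
        cfg.max_epochs_stage1,
        rng,
        history,
        stage=1,
        gamma_monitor=gamma_monitor,
    )
    return unet, history


@dataclass
class TwoStepResult:
    """Outcome of the two-step learning process for one fold."""

    network: UNet  # fine-tuned, to be used with the TDM
    stage1_network: UNet  # snapshot after stage 1 (the "U-net" ablation variant)
    tdm: TDMLayer
    history: TrainingHistory
    fold: FoldSplit


def two_step_train(
    dataset: PreparedDataset,
    fold: FoldSplit,
    cfg: TrainingConfig,
    spec: UNetSpec = UNetSpec(),
    gamma_monitor=None,
) -> TwoStepResult:
    """Stage-1 training, TDM computation and attachment, then fine-tuning.

    The TDM comes from the 260 mm open square: reference dose over the
    stage-1 network's own inference of that beam.  Fine-tuning updates all
    U-net parameters at the lower learning rate; the TDM never changes.
    """
    seed = np.random.SeedSequence([cfg.rng_seed & 0x7FFFFFFF, fold.fold_id, 0])
    unet = UNet(spec, np.random.default_rng(seed))
    unet, history = train_stage1(dataset, fold, unet, cfg, gamma_monitor)
    stage1_snapshot = unet.copy()

    inferred_cal = unet.forward(dataset.cal_mpi_260)[0, :, :, 0].astype(np.float64)
    tdm = compute_tdm(dataset.cal_ppd_260, inferred_cal)
    history.attach_epoch = len(history)

    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.rng_seed & 0x7FFFFFFF, fold.fold_id, 2])
    )
    _fit(
        unet,
        tdm,
        dataset.X[fold.train],
        dataset.Y[fold.train],
        dataset.X[fold.validation],
        dataset.Y[fold.validation],
        cfg,
        cfg.lr_finetune,
        cfg.max_epochs_finetune,
        rng,
        history,
        stage=2,
        gamma_monitor=gamma_monitor,
    )
    return TwoStepResult(
        network=unet, stage1_network=stage1_snapshot, tdm=tdm, history=history, fold=fold
    )


def select_model(cv_results: list[dict]) -> dict:
    """Pick the fold with the lowest mean test gamma.

    Each entry needs ``fold_id``, ``mean_gamma`` and ``passing_rate``.  Ties
    break toward the higher passing rate, then the lower fold id.
    """
    if not cv_results:
        raise ValueError("no cross-validation results")
    for r in cv_results:
        if "mean_gamma" not in r or "passing_rate" not in r:
            raise ValueError("missing test gamma statistics in a fold result")
    return min(cv_results, key=lambda r: (r["mean_gamma"], -r["passing_rate"], r["fold_id"]))
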