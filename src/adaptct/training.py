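"""Composite-loss training and whole-volume synthesis.

The loss is a weighted sum of three terms,

    L = λ1·L_MAE + λ2·L_MSE + λ3·L_SSIM,      λ = (100, 1, 1) by default,

where MAE and MSE are averaged over the body region only and the SSIM term
is ``1 - SSIM`` over the full image (windowed local SSIM with a Gaussian
window, so a perfect prediction gives exactly zero loss). Optimization uses
Adam; stochastic augmentation draws one of {rotation, translation,
horizontal flip} with probability ``augment_prob`` and applies the same
geometric transform to input channels and target.

Whole-volume synthesis runs slice-wise 2.5-D inference, inverts the frozen
Z-score normalization back to HU, and composites air (-1000 HU) outside the
body mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .errors import DegenerateInputError, ModelStateError, TrainingDivergedError
from .phantom import SyntheticCase
from .preprocess import (
    HU_AIR,
    NormStats,
    body_mask,
    estimate_norm_stats,
    stack_adjacent_slices,
    zscore,
    inverse_zscore,
)
from .unetpp import SynthesisModel
from .volume import Volume

__all__ = [
    "LossWeights",
    "LossReport",
    "TrainConfig",
    "composite_loss",
    "augment",
    "train",
    "synthesize_volume",
]

#: fixed dynamic range (in normalized units) for the SSIM loss stabilizers
SSIM_LOSS_RANGE = 4.0
_SSIM_KERNEL = ad.gaussian_kernel1d(sigma=1.5, radius=5)  # 11-tap Gaussian window


@dataclass
class LossWeights:
    lambda1: float = 100.0  # MAE
    lambda2: float = 1.0    # MSE
    lambda3: float = 1.0    # SSIM

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class LossReport:
    l_mae: float
    l_mse: float
    l_ssim: float
    total: float

    @classmethod
    def from_terms(cls, l_mae, l_mse, l_ssim, w: LossWeights) -> "LossReport":
        return cls(
            l_mae=l_mae,
            l_mse=l_mse,
            l_ssim=l_ssim,
            total=w.lambda1 * l_mae + w.lambda2 * l_mse + w.lambda3 * l_ssim,
        )


@dataclass
class TrainConfig:
    """Optimization protocol; defaults follow the full-scale recipe
    (Adam, lr 1e-4, 200 epochs, augmentation probability 0.5)."""

    learning_rate: float = 1e-4
    epochs: int = 200
    augment_prob: float = 0.5
    batch_size: int = 8
    seed: int = 0
    val_fraction: float = 0.15
    rotation_range_deg: float = 10.0
    translation_frac: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.augment_prob <= 1.0:
            raise ValueError("augment_prob must be in [0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


# ---------------------------------------------------------------------------
# composite loss
# ---------------------------------------------------------------------------

def _ssim_loss_graph(pred: ad.Tensor, target: ad.Tensor) -> ad.Tensor:
    """1 - mean windowed SSIM over the full image, differentiable."""
    L = SSIM_LOSS_RANGE
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    mu_x = ad.gaussian_blur2d(pred, _SSIM_KERNEL)
    mu_y = ad.gaussian_blur2d(target, _SSIM_KERNEL)
    sig_x = ad.gaussian_blur2d(pred * pred, _SSIM_KERNEL) - mu_x * mu_x
    sig_y = ad.gaussian_blur2d(target * target, _SSIM_KERNEL) - mu_y * mu_y
    sig_xy = ad.gaussian_blur2d(pred * target, _SSIM_KERNEL) - mu_x * mu_y
    num = (2.0 * mu_x * mu_y + c1) * (2.0 * sig_xy + c2)
    den = (mu_x * mu_x + mu_y * mu_y + c1) * (sig_x + sig_y + c2)
    return 1.0 - ad.mean(num / den)


def composite_loss_graph(
    pred: ad.Tensor, target: ad.Tensor, body: np.ndarray, w: LossWeights
) -> tuple[ad.Tensor, LossReport]:
    """Differentiable composite loss on channel-first (1, N, H, W) tensors.

    Returns the scalar graph node and a float report of the unweighted terms.
    """
    mask = np.asarray(body, dtype=pred.data.dtype)
    n_body = mask.sum()
    if n_body == 0:
        raise DegenerateInputError("empty body mask in composite loss")
    diff = pred - target
    l_mae = ad.total(absolute_masked(diff, mask)) * (1.0 / n_body)
    l_mse = ad.total(diff * diff * ad.Tensor(mask)) * (1.0 / n_body)
    l_ssim = _ssim_loss_graph(pred, target)
    total_t = w.lambda1 * l_mae + w.lambda2 * l_mse + w.lambda3 * l_ssim
    report = LossReport.from_terms(l_mae.item(), l_mse.item(), l_ssim.item(), w)
    return total_t, report


def absolute_masked(diff: ad.Tensor, mask: np.ndarray) -> ad.Tensor:
    return ad.absolute(diff) * ad.Tensor(mask)


def composite_loss(
    pred: np.ndarray | Volume,
    target: np.ndarray | Volume,
    body: np.ndarray | Volume,
    w: LossWeights | None = None,
) -> LossReport:
    """Evaluate the composite loss on arrays (2-D slices or slice batches)."""
    w = w if w is not None else LossWeights()
    p = np.asarray(pred.data if isinstance(pred, Volume) else pred, dtype=np.float64)
    t = np.asarray(target.data if isinstance(target, Volume) else target, dtype=np.float64)
    b = np.asarray(body.data if isinstance(body, Volume) else body, dtype=bool)
    if p.shape != t.shape or p.shape != b.shape:
        raise DegenerateInputError("pred/target/body shapes must agree")
    if p.ndim == 2:
        p, t, b = p[None], t[None], b[None]
    _, report = composite_loss_graph(ad.Tensor(p[None]), ad.Tensor(t[None]), b[None], w)
    return report


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _transform_channels(arr: np.ndarray, kind: str, amount, order: int = 1) -> np.ndarray:
    """Apply one geometric transform to every channel of (C, H, W)."""
    if kind == "flip":
        return arr[:, :, ::-1].copy()
    if kind == "rotate":
        return np.stack(
            [
                ndimage.rotate(c, amount, reshape=False, order=order, mode="nearest")
                for c in arr
            ]
        ).astype(arr.dtype)
    if kind == "translate":
        dy, dx = amount
        return np.stack(
            [ndimage.shift(c, (dy, dx), order=order, mode="nearest") for c in arr]
        ).astype(arr.dtype)
    raise ValueError(kind)


def augment(
    pair: tuple[np.ndarray, np.ndarray],
    p: float = 0.5,
    seed: int | np.random.Generator = 0,
    rotation_range_deg: float = 10.0,
    translation_frac: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """With probability ``p`` apply one transform from {rotation, translation,
    horizontal flip}, identically to input stack and target."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stack, target = pair
    stack = np.asarray(stack)
    target = np.asarray(target)
    tgt3 = target if target.ndim == 3 else target[None]
    if rng.random() >= p:
        return stack, target
    kind = rng.choice(["rotate", "translate", "flip"])
    if kind == "rotate":
        amount = float(rng.uniform(-rotation_range_deg, rotation_range_deg))
    elif kind == "translate":
        h, w = stack.shape[-2:]
        amount = (
            float(rng.uniform(-translation_frac, translation_frac) * h),
            float(rng.uniform(-translation_frac, translation_frac) * w),
        )
    else:
        amount = None
    new_stack = _transform_channels(stack, kind, amount)
    new_tgt = _transform_channels(tgt3, kind, amount)
    return new_stack, (new_tgt if target.ndim == 3 else new_tgt[0])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _case_slices(case: SyntheticCase, stats: NormStats):
    """Yield (input stack, target slice, body slice) in normalized units."""
    cbct_n = zscore(case.cbct, stats)
    pct_n = zscore(case.pct, stats)
    body = case.body.data.astype(bool)
    for k in range(case.pct.shape[0]):
        stack = stack_adjacent_slices(cbct_n, k).channels
        yield stack, pct_n.data[k].astype(np.float32), body[k]


def build_training_arrays(cases: list[SyntheticCase], stats: NormStats):
    xs, ys, ms = [], [], []
    for case in cases:
        for stack, tgt, msk in _case_slices(case, stats):
            xs.append(stack)
            ys.append(tgt)
            ms.append(msk)
    return np.stack(xs), np.stack(ys), np.stack(ms)


def _eval_loss(model, xs, ys, ms, w: LossWeights, batch: int) -> LossReport:
    terms = np.zeros(3)
    n = 0
    for s in range(0, len(xs), batch):
        xb, yb, mb = xs[s : s + batch], ys[s : s + batch], ms[s : s + batch]
        pred = model.forward_graph(ad.Tensor(np.ascontiguousarray(xb.transpose(1, 0, 2, 3))))
        _, rep = composite_loss_graph(pred, ad.Tensor(yb[None]), mb[None], w)
        terms += np.array([rep.l_mae, rep.l_mse, rep.l_ssim]) * len(xb)
        n += len(xb)
    terms /= n
    return LossReport.from_terms(*terms, w)


def train(
    model: SynthesisModel,
    dataset: list[SyntheticCase],
    cfg: TrainConfig | None = None,
    weights: LossWeights | None = None,
    stats: NormStats | None = None,
    verbose: bool = False,
) -> tuple[SynthesisModel, list[dict]]:
    """Train the generator on paired synthetic cases.

    The validation split is the trailing ``val_fraction`` of the dataset.
    Normalization statistics are estimated from the training split's body
    voxels (planning CT) unless given, frozen, and attached to the model so
    synthesis can invert them. Returns the model and a per-epoch history.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    weights = weights if weights is not None else LossWeights()
    if not dataset:
        raise DegenerateInputError("empty training dataset")
    n_val = int(round(len(dataset) * cfg.val_fraction))
    n_val = min(max(n_val, 1 if len(dataset) > 1 else 0), len(dataset) - 1)
    train_cases = dataset[: len(dataset) - n_val] if n_val else dataset
    val_cases = dataset[len(dataset) - n_val :] if n_val else []

    if stats is None:
        stats = estimate_norm_stats(
            [c.pct for c in train_cases], [c.body for c in train_cases]
        )
    xs, ys, ms = build_training_arrays(train_cases, stats)
    if val_cases:
        xv, yv, mv = build_training_arrays(val_cases, stats)

    rng = np.random.default_rng(cfg.seed)
    opt = ad.Adam(model.parameters, lr=cfg.learning_rate)
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(xs))
        epoch_terms = np.zeros(3)
        n_seen = 0
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            xb = xs[idx].copy()
            yb = ys[idx].copy()
            mb = ms[idx].astype(np.float32)
            if cfg.augment_prob > 0:
                for b in range(len(idx)):
                    pair = np.concatenate([yb[b][None], mb[b][None]])
                    xa, pa = augment(
                        (xb[b], pair),
                        cfg.augment_prob,
                        rng,
                        cfg.rotation_range_deg,
                        cfg.translation_frac,
                    )
                    xb[b], yb[b], mb[b] = xa, pa[0], pa[1]
            mbin = mb > 0.5
            if not mbin.any():
                continue
            opt.zero_grad()
            pred = model.forward_graph(
                ad.Tensor(np.ascontiguousarray(xb.transpose(1, 0, 2, 3)))
            )
            loss_t, rep = composite_loss_graph(
                pred, ad.Tensor(yb[None]), mbin[None], weights
            )
            if not np.isfinite(rep.total):
                raise TrainingDivergedError(epoch)
            if loss_t.requires_grad and rep.total != 0.0:
                loss_t.backward()
                opt.step()
            epoch_terms += np.array([rep.l_mae, rep.l_mse, rep.l_ssim]) * len(idx)
            n_seen += len(idx)
        entry = {"epoch": epoch}
        tr = LossReport.from_terms(*(epoch_terms / max(n_seen, 1)), weights)
        entry.update(train_mae=tr.l_mae, train_mse=tr.l_mse, train_ssim=tr.l_ssim,
                     train_total=tr.total)
        if val_cases:
            vr = _eval_loss(model, xv, yv, mv, weights, cfg.batch_size)
            if not np.isfinite(vr.total):
                raise TrainingDivergedError(epoch)
            entry.update(val_mae=vr.l_mae, val_mse=vr.l_mse, val_ssim=vr.l_ssim,
                         val_total=vr.total)
        history.append(entry)
        if verbose:
            msg = " ".join(f"{k}={v:.5g}" for k, v in entry.items() if k != "epoch")
            print(f"epoch {epoch + 1}/{cfg.epochs} {msg}")
    model.trained = True
    model.norm_stats = stats
    return model, history


# ---------------------------------------------------------------------------
# whole-volume synthesis
# ---------------------------------------------------------------------------

def synthesize_volume(
    model: SynthesisModel,
    cbct: Volume,
    stats: NormStats | None = None,
    batch_size: int = 8,
) -> Volume:
    """Slice-wise 2.5-D synthesis of a whole volume, restored to HU.

    Voxels outside the CBCT body outline are set to -1000 HU.
    """
    if not getattr(model, "trained", False):
        raise ModelStateError("model is untrained; train it or load a checkpoint")
    if stats is None:
        stats = getattr(model, "norm_stats", None)
    if stats is None:
        raise ModelStateError("no normalization statistics available for synthesis")
    cbct_n = zscore(cbct, stats)
    stacks = np.stack(
        [stack_adjacent_slices(cbct_n, k).channels for k in range(cbct.shape[0])]
    )
    preds = []
    for s in range(0, len(stacks), batch_size):
        preds.append(model.predict(stacks[s : s + batch_size])[:, 0])
    pred_n = Volume(np.concatenate(preds), cbct.spacing, cbct.origin)
    act = inverse_zscore(pred_n, stats)
    body = body_mask(cbct)
    out = act.data.copy()
    out[~body.data.astype(bool)] = HU_AIR
    return Volume(out.astype(np.float32), cbct.spacing, cbct.origin)
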