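"""Loss construction, optimisation loop and k-fold cross-validation.

The training objective is the sum of a soft multi-class Dice loss and the
per-pixel cross-entropy, ``L_total = L_dice + L_CE``, optionally extended by
deep supervision: auxiliary (dice + CE) terms on the intermediate decoder
outputs against nearest-neighbour-downsampled targets, each scaled by a
weight.  The logged decomposition is exact at every step:
``l_total == l_dice + l_ce + sum_i w_i * l_aux_i``.

The reference protocol is fivefold cross-validation (80/20 slice-level
splits) repeated five times with averaged results; :func:`run_crossval`
implements the bookkeeping at any (k, repeats) so it can run at desk scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .labels import STRUCTURES
from .model import VSTConfig, VSTNet
from .nn import Adam, Tensor, gather_channel, log_softmax, softmax
from .phantom import PhantomSample
from .saliency import SaliencyConfig, compute_saliency

DICE_EPS = 1e-5


@dataclass
class TrainConfig:
    """Optimisation settings; defaults follow the reference protocol
    (Adam, lr 0.01, momentum coefficient 0.1, 1000 epochs of 250 iterations
    at batch size 12).  Desk-scale runs override the schedule."""

    epochs: int = 1000
    iterations_per_epoch: int = 250
    batch_size: int = 12
    learning_rate: float = 0.01
    optimizer_momentum: float = 0.1  # Adam beta1
    beta2: float = 0.999
    aux_loss_weights: tuple[float, ...] = (0.5, 0.25, 0.125)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.iterations_per_epoch, self.batch_size) < 1:
            raise ValueError("epochs, iterations and batch size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if any(not 0.0 <= w <= 1.0 for w in self.aux_loss_weights):
            raise ValueError("aux weights must lie in [0, 1]")

    @property
    def total_steps(self) -> int:
        return self.epochs * self.iterations_per_epoch


@dataclass
class LossTerms:
    l_dice: float
    l_ce: float
    l_aux: list[float] = field(default_factory=list)
    aux_weights: list[float] = field(default_factory=list)
    l_total: float = 0.0


@dataclass
class FoldSplit:
    k: int
    assignments: np.ndarray  # item index -> fold id
    repeat_index: int = 1

    def fold_items(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_val(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        val = self.fold_items(fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, val


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    if target.min() < 0 or target.max() >= n_classes:
        raise ValueError(
            f"target labels outside [0, {n_classes}): "
            f"[{target.min()}, {target.max()}]"
        )
    return np.moveaxis(np.eye(n_classes, dtype=np.float32)[target], -1, 1)


def dice_loss(scores: Tensor | np.ndarray, target: np.ndarray,
              eps: float = DICE_EPS) -> Tensor:
    """Soft Dice loss averaged over foreground classes.

    Per class c: ``1 - (2 sum(p_c g_c) + eps) / (sum(p_c) + sum(g_c) + eps)``
    with p the softmax probabilities and g the one-hot target; the background
    class is excluded from the average.
    """
    scores = scores if isinstance(scores, Tensor) else Tensor(scores)
    n_classes = scores.data.shape[1]
    target = np.asarray(target)
    if target.ndim == scores.data.ndim - 2:
        target = target[None]
    g = _one_hot(target, n_classes)
    p = softmax(scores, axis=1)
    axes = (0,) + tuple(range(2, scores.data.ndim))
    inter = (p * g).sum(axis=axes)
    denom = p.sum(axis=axes) + Tensor(g.sum(axis=axes))
    dice = (inter * 2.0 + eps) / (denom + eps)
    fg = dice[slice(1, n_classes)]
    return 1.0 - fg.mean()


def cross_entropy_loss(scores: Tensor | np.ndarray, target: np.ndarray) -> Tensor:
    """Mean per-pixel negative log-likelihood of the target labels."""
    scores = scores if isinstance(scores, Tensor) else Tensor(scores)
    n_classes = scores.data.shape[1]
    target = np.asarray(target)
    if target.ndim == scores.data.ndim - 2:
        target = target[None]
    if target.min() < 0 or target.max() >= n_classes:
        raise ValueError("target labels out of range")
    logp = log_softmax(scores, axis=1)
    return -gather_channel(logp, target).mean()


def _downsample_labels(target: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbour label downsampling for auxiliary supervision."""
    return target[..., ::factor, ::factor]


def total_loss(scores: Tensor, target: np.ndarray,
               aux_outputs: list[Tensor] = (),
               aux_weights: tuple[float, ...] = ()) -> tuple[Tensor, LossTerms]:
    """L_total = L_dice + L_CE + sum_i w_i (dice + CE on aux output i)."""
    aux_outputs = list(aux_outputs)
    weights = list(aux_weights)[: len(aux_outputs)]
    if aux_outputs and len(weights) != len(aux_outputs):
        raise ValueError(
            f"{len(aux_outputs)} auxiliary outputs but {len(weights)} weights"
        )
    target = np.asarray(target)
    if target.ndim == 2:
        target = target[None]
    l_dice = dice_loss(scores, target)
    l_ce = cross_entropy_loss(scores, target)
    total = l_dice + l_ce
    aux_vals = []
    for w, aux in zip(weights, aux_outputs):
        factor = target.shape[-1] // aux.data.shape[-1]
        t_small = _downsample_labels(target, factor)
        l_aux = dice_loss(aux, t_small) + cross_entropy_loss(aux, t_small)
        aux_vals.append(float(l_aux.data))
        total = total + w * l_aux
    terms = LossTerms(
        l_dice=float(l_dice.data),
        l_ce=float(l_ce.data),
        l_aux=aux_vals,
        aux_weights=weights,
        l_total=float(total.data),
    )
    return total, terms


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def make_folds(n_items: int, k: int, seed: int, repeat_index: int = 1) -> FoldSplit:
    """Disjoint covering partition into k folds with sizes differing by <= 1."""
    if n_items < k:
        raise ValueError(f"cannot split {n_items} items into {k} folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed, repeat_index]))
    perm = rng.permutation(n_items)
    assignments = np.empty(n_items, dtype=np.int64)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignments[chunk] = fold
    return FoldSplit(k=k, assignments=assignments, repeat_index=repeat_index)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _normalize(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo == 0:
        return np.zeros_like(img, dtype=np.float32)
    return ((img - lo) / (hi - lo)).astype(np.float32)


def prepare_inputs(samples: list[PhantomSample], need_saliency: bool,
                   saliency_config: SaliencyConfig | None = None):
    """Min-max-normalised images, masks and (optionally) saliency maps."""
    images = [_normalize(s.image.data) for s in samples]
    masks = [s.mask.data for s in samples]
    sals = None
    if need_saliency:
        cfg = saliency_config or SaliencyConfig()
        sals = [_normalize(compute_saliency(im, cfg).sm) for im in images]
    return images, masks, sals


def foreground_dsc(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean Dice over the foreground labels present in the target."""
    vals = []
    for lab in STRUCTURES:
        a = pred == lab
        b = target == lab
        if not b.any() and not a.any():
            continue
        vals.append(2.0 * np.logical_and(a, b).sum() / max(a.sum() + b.sum(), 1))
    return float(np.mean(vals)) if vals else float("nan")


def train_model(samples: list[PhantomSample], model_config: VSTConfig,
                train_config: TrainConfig, steps: int | None = None,
                precomputed=None) -> tuple[VSTNet, list[LossTerms]]:
    """Train a network on phantom slices; deterministic under a fixed seed.

    ``steps`` overrides the full ``epochs * iterations_per_epoch`` schedule
    (desk-scale runs use a few hundred steps).  Raises on non-finite loss.
    """
    if not samples and precomputed is None:
        raise ValueError("need at least one training sample")
    cfg = train_config
    if precomputed is None:
        images, masks, sals = prepare_inputs(samples, model_config.mode == "vst")
    else:
        images, masks, sals = precomputed
    n = len(images)
    model = VSTNet(model_config, seed=cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               beta1=cfg.optimizer_momentum, beta2=cfg.beta2)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xB07]))
    n_steps = cfg.total_steps if steps is None else int(steps)
    history: list[LossTerms] = []
    for step in range(n_steps):
        idx = rng.integers(0, n, size=min(cfg.batch_size, n))
        img = np.stack([images[i] for i in idx])
        tgt = np.stack([masks[i] for i in idx])
        sal = np.stack([sals[i] for i in idx]) if sals is not None else None
        out = model(img, sal)
        loss, terms = total_loss(out["scores"], tgt, out["aux"],
                                 cfg.aux_loss_weights)
        if not np.isfinite(terms.l_total):
            raise FloatingPointError(f"training diverged at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(terms)
    return model, history


def evaluate_dsc(model: VSTNet, images, masks, sals=None) -> float:
    """Mean foreground DSC of the model over a list of slices."""
    vals = []
    for i, (img, tgt) in enumerate(zip(images, masks)):
        sal = None if sals is None else sals[i]
        pred = model.predict_labels(img[None], None if sal is None else sal[None])[0]
        vals.append(foreground_dsc(pred, tgt))
    return float(np.mean(vals))


def run_crossval(samples: list[PhantomSample], model_config: VSTConfig,
                 train_config: TrainConfig, k: int = 5, repeats: int = 5,
                 steps: int | None = None) -> dict:
    """k-fold cross-validation repeated ``repeats`` times, averaged.

    Returns a report with per-repeat, per-fold validation DSC, the within-
    repeat means, and the across-repeat final mean, plus fold assignments
    for provenance.
    """
    if not samples:
        raise ValueError("dataset must be nonempty")
    images, masks, sals = prepare_inputs(samples, model_config.mode == "vst")
    report = {"k": k, "repeats": repeats, "per_repeat": [], "mean_dsc": None}
    repeat_means = []
    for rep in range(1, repeats + 1):
        split = make_folds(len(samples), k, train_config.seed, repeat_index=rep)
        fold_entries = []
        for fold in range(k):
            tr, va = split.train_val(fold)
            pre = ([images[i] for i in tr], [masks[i] for i in tr],
                   None if sals is None else [sals[i] for i in tr])
            fold_cfg = dataclasses.replace(
                train_config, seed=train_config.seed + 1000 * rep + fold
            )
            model, _ = train_model([], model_config, fold_cfg, steps=steps,
                                   precomputed=pre)
            dsc = evaluate_dsc(model,
                               [images[i] for i in va], [masks[i] for i in va],
                               None if sals is None else [sals[i] for i in va])
            fold_entries.append({"fold": fold, "n_val": int(len(va)),
                                 "val_dsc": dsc})
        mean_rep = float(np.mean([f["val_dsc"] for f in fold_entries]))
        repeat_means.append(mean_rep)
        report["per_repeat"].append({
            "repeat": rep,
            "assignments": split.assignments.tolist(),
            "folds": fold_entries,
            "mean_dsc": mean_rep,
        })
    report["mean_dsc"] = float(np.mean(repeat_means))
    return report
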