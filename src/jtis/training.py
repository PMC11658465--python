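"""Multitask training: joint objective, LR schedule, FGM adversarial steps.

Each optimizer step processes a batch twice when adversarial training is on:
once clean, then once with the token-embedding table perturbed by
``r_adv = ε · g / ‖g‖₂`` (g = gradient of the joint loss at the embedding
layer).  Gradients from the two passes accumulate, the embedding table is
restored exactly, the accumulated gradient is clipped, and AdamW updates two
parameter groups (encoder vs. task heads) under a linear warmup/decay
schedule.  With ε = 0 the adversarial pass is skipped entirely, making the
step identical to plain fine-tuning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from ._autograd import Tensor
from .model import ModelBundle, TASKS, batch_task_losses, joint_loss
from .samples import EncoderConfig, LabelSchema, NONE_LABEL, PairSample

__all__ = [
    "TrainConfig",
    "tiny_train_config",
    "AdamW",
    "lr_at",
    "fgm_perturbation",
    "train_step",
    "train_model",
]


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the reference fine-tuning recipe for a pretrained
    biomedical encoder (100 epochs, batch 2, encoder LR 2e-5, head LR 1e-4,
    6% linear warmup then decay to zero, gradient clipping at norm 1,
    auxiliary-task weights η = 0.1, FGM ε = 1).  Desk-scale runs with the
    randomly initialized tiny encoder use :func:`tiny_train_config`.
    """

    epochs: int = 100
    batch_size: int = 2
    encoder_lr: float = 2e-5
    head_lr: float = 1e-4
    warmup_fraction: float = 0.06
    clip_norm: float = 1.0
    loss_weights: dict[str, float] = field(
        default_factory=lambda: {t: 0.1 for t in TASKS}
    )
    fgm_epsilon: float = 1.0
    weight_decay: float = 0.01
    seed: int = 0
    primary_task: str = "RE"
    tnt_uses_none_negatives: bool = True
    checkpoint_selection: str = "best"  # or "last"

    def __post_init__(self) -> None:
        if not (0.0 <= self.warmup_fraction < 1.0):
            raise ValueError("warmup_fraction must be in [0, 1)")
        if self.fgm_epsilon < 0:
            raise ValueError("fgm_epsilon must be >= 0")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be > 0")
        if self.primary_task not in ("RE", "TNT"):
            raise ValueError("primary_task must be RE or TNT")


def tiny_train_config(primary_task: str = "RE", seed: int = 0, **overrides) -> TrainConfig:
    """Training configuration for the randomly initialized tiny encoder.

    A from-scratch 2-layer/h=64 model needs a much larger learning rate
    (3e-3 for both groups), a larger batch (8) and fewer epochs (40) than a
    pretrained encoder; everything else (warmup, clipping, η = 0.1,
    FGM ε = 1) keeps the reference recipe.
    """
    cfg = TrainConfig(
        epochs=40,
        batch_size=8,
        encoder_lr=3e-3,
        head_lr=3e-3,
        seed=seed,
        primary_task=primary_task,
    )
    return replace(cfg, **overrides)


def lr_at(step: int, total_steps: int, peak_lr: float, warmup_fraction: float) -> float:
    """Piecewise-linear schedule: 0 → peak over the warmup steps, then
    peak → 0 at ``total_steps``."""
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    if not (0 <= step <= total_steps):
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    warmup = math.ceil(warmup_fraction * total_steps)
    if warmup > 0 and step < warmup:
        return peak_lr * step / warmup
    if step >= total_steps:
        return 0.0
    return peak_lr * (total_steps - step) / max(total_steps - warmup, 1)


def fgm_perturbation(gradient: np.ndarray, epsilon: float) -> np.ndarray:
    """FGM perturbation ε·g/‖g‖₂; the zero vector when g (or ε) vanishes."""
    g = np.asarray(gradient, dtype=np.float64)
    if epsilon == 0.0:
        return np.zeros_like(g)
    norm = float(np.linalg.norm(g))
    if norm == 0.0:
        return np.zeros_like(g)
    return (epsilon / norm) * g


class AdamW(object):
    """Decoupled-weight-decay Adam over named parameter groups."""

    def __init__(
        self,
        groups: Sequence[tuple[list[Tensor], float]],
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.groups = [(list(params), peak) for params, peak in groups]
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {id(p): np.zeros_like(p.data) for params, _ in self.groups for p in params}
        self.v = {id(p): np.zeros_like(p.data) for params, _ in self.groups for p in params}

    def step(self, lr_scale: float) -> None:
        """One update; each group's LR is its peak times ``lr_scale``."""
        b1, b2 = self.betas
        self.t += 1
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for params, peak in self.groups:
            lr = peak * lr_scale
            for p in params:
                if p.grad is None:
                    continue
                m = self.m[id(p)]
                v = self.v[id(p)]
                m *= b1
                m += (1 - b1) * p.grad
                v *= b2
                v += (1 - b2) * p.grad**2
                update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
                if p.data.ndim >= 2 and self.weight_decay:
                    update = update + self.weight_decay * p.data
                p.data -= lr * update


def clip_gradients(params: Iterable[Tensor], max_norm: float) -> float:
    """Global-norm gradient clipping; returns the pre-clip norm."""
    grads = [p.grad for p in params if p.grad is not None]
    total = math.sqrt(sum(float((g**2).sum()) for g in grads))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return total


def _joint(bundle: ModelBundle, batch: Sequence[PairSample], config: TrainConfig) -> Tensor:
    losses = batch_task_losses(
        bundle, batch, tnt_uses_none_negatives=config.tnt_uses_none_negatives
    )
    primary = losses.pop(config.primary_task)
    return joint_loss(primary, losses, config.loss_weights)


def train_step(
    batch: Sequence[PairSample],
    bundle: ModelBundle,
    optimizer: AdamW,
    config: TrainConfig,
    lr_scale: float,
) -> dict[str, float]:
    """One optimizer step: clean pass, optional FGM adversarial pass with
    gradient accumulation and exact embedding restoration, clip, update."""
    bundle.zero_grad()
    clean = _joint(bundle, batch, config)
    clean_val = clean.item()
    if not math.isfinite(clean_val):
        raise RuntimeError(
            f"non-finite clean loss {clean_val} on doc(s) "
            f"{sorted({s.doc_id for s in batch})}"
        )
    clean.backward()

    adv_val = math.nan
    if config.fgm_epsilon > 0.0:
        emb = bundle.encoder.tok_emb
        g = emb.grad.copy() if emb.grad is not None else np.zeros_like(emb.data)
        r_adv = fgm_perturbation(g, config.fgm_epsilon)
        saved = emb.data.copy()
        emb.data += r_adv
        try:
            adv = _joint(bundle, batch, config)
            adv_val = adv.item()
            if not math.isfinite(adv_val):
                raise RuntimeError(f"non-finite adversarial loss {adv_val}")
            adv.backward()
        finally:
            emb.data[...] = saved

    grad_norm = clip_gradients(bundle.parameters(), config.clip_norm)
    optimizer.step(lr_scale)
    return {"clean_loss": clean_val, "adv_loss": adv_val, "grad_norm": grad_norm}


def _doc_batches(
    samples: Sequence[PairSample], batch_size: int, rng: np.random.Generator
) -> list[list[PairSample]]:
    """Shuffle documents, keep each document's samples contiguous, chunk."""
    by_doc: dict[str, list[PairSample]] = {}
    for s in samples:
        by_doc.setdefault(s.doc_id, []).append(s)
    doc_ids = list(by_doc)
    rng.shuffle(doc_ids)
    flat = [s for d in doc_ids for s in by_doc[d]]
    return [flat[i : i + batch_size] for i in range(0, len(flat), batch_size)]


def dev_metrics(bundle: ModelBundle, dev_samples: Sequence[PairSample]) -> dict[str, float]:
    """Sample-level dev metrics: relation micro-F1 at the pair and pair+type
    tiers, plus TNT accuracy over gold-related samples."""
    out = {"tier1_f1": 0.0, "tier2_f1": 0.0, "tnt_acc": 0.0}
    if not dev_samples:
        return out
    pred, _ = bundle.predict_re(dev_samples)
    gold = [s.re_label for s in dev_samples]
    pred_pos = sum(1 for p in pred if p != NONE_LABEL)
    gold_pos = sum(1 for g in gold if g != NONE_LABEL)
    tp1 = sum(1 for p, g in zip(pred, gold) if p != NONE_LABEL and g != NONE_LABEL)
    tp2 = sum(1 for p, g in zip(pred, gold) if p == g and g != NONE_LABEL)
    for tier, tp in (("tier1_f1", tp1), ("tier2_f1", tp2)):
        denom = pred_pos + gold_pos
        out[tier] = 2 * tp / denom if denom else 0.0
    related = [s for s in dev_samples if s.re_label != NONE_LABEL]
    if related:
        tnt_pred, _ = bundle.predict_tnt(related)
        out["tnt_acc"] = sum(
            1 for p, s in zip(tnt_pred, related) if p == s.tnt_label
        ) / len(related)
    return out


def train_model(
    train_samples: Sequence[PairSample],
    dev_samples: Sequence[PairSample],
    schema: LabelSchema,
    encoder_config: EncoderConfig,
    config: TrainConfig,
) -> tuple[ModelBundle, list[dict[str, float]]]:
    """Run the full multitask loop; returns the trained bundle and the
    per-epoch history (losses + dev metrics).

    The returned bundle is the best-dev checkpoint (pair+type F1 for an
    RE-primary model, TNT accuracy for a TNT-primary model) unless
    ``config.checkpoint_selection == "last"``.
    """
    if not train_samples:
        raise ValueError("empty training sample set")
    rng = np.random.default_rng(config.seed)
    bundle = ModelBundle.create(
        schema, encoder_config, primary_task=config.primary_task, seed=config.seed
    )
    optimizer = AdamW(
        [
            (bundle.encoder_parameters(), config.encoder_lr),
            (bundle.head_parameters(), config.head_lr),
        ],
        weight_decay=config.weight_decay,
    )
    steps_per_epoch = math.ceil(len(train_samples) / config.batch_size)
    total_steps = steps_per_epoch * config.epochs
    select_key = "tier2_f1" if config.primary_task == "RE" else "tnt_acc"

    history: list[dict[str, float]] = []
    best_score, best_state = -1.0, None
    step = 0
    for epoch in range(config.epochs):
        epoch_losses: list[float] = []
        for batch in _doc_batches(train_samples, config.batch_size, rng):
            scale = lr_at(step, total_steps, 1.0, config.warmup_fraction)
            metrics = train_step(batch, bundle, optimizer, config, scale)
            epoch_losses.append(metrics["clean_loss"])
            step += 1
        record = {"epoch": epoch, "mean_clean_loss": float(np.mean(epoch_losses))}
        record.update(dev_metrics(bundle, dev_samples))
        history.append(record)
        if record[select_key] >= best_score:
            best_score = record[select_key]
            best_state = bundle.state_dict()
    if config.checkpoint_selection == "best" and best_state is not None:
        bundle.load_state_dict(best_state)
    return bundle, history
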