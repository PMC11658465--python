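"""Task heads, losses, and the joint multitask objective.

Four tasks share one encoder:

* CR — for a pair of marked mentions (m_i, m_j), represented by the encoder
  vectors at their opening markers, a bilinear layer scores coreference:
  ``P_CR = softmax(m_i A m_j + b)`` with ``A`` of shape (h, 2, h).
* EPT / RE / TNT — document-level classifications from the classifier-token
  vector V[0]: ``P_t = softmax(W_t V[0] + b_t)``.

All tasks use cross-entropy.  The training objective for a model with
primary task p is ``L = L_p + Σ_t η_t L_t`` over the auxiliary tasks t.
Separate models are trained with RE and with TNT as the primary task; at
inference the RE model proposes relations and the TNT model types the
novelty of pairs the RE model found related.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._autograd import Tensor, gather_rows, no_grad, softmax
from .corpus import NOVEL, NOT_NOVEL
from .encoder import TinyTransformerEncoder
from .samples import EncoderConfig, LabelSchema, NONE_LABEL, PairSample

__all__ = [
    "CRHead",
    "DocHead",
    "ModelBundle",
    "cr_probs",
    "doc_probs",
    "cross_entropy_loss",
    "joint_loss",
    "batch_task_losses",
    "TASKS",
]

TASKS = ("CR", "EPT", "RE", "TNT")


class CRHead:
    """Bilinear coreference scorer: logit_c = m_i^T A[:, c, :] m_j + b_c."""

    def __init__(self, hidden_size: int, rng: np.random.Generator):
        self.A = Tensor.param(rng.normal(0.0, 0.02, size=(2, hidden_size, hidden_size)))
        self.b = Tensor.param(np.zeros(2))

    def parameters(self) -> list[Tensor]:
        return [self.A, self.b]

    def logits(self, m_i: Tensor, m_j: Tensor) -> Tensor:
        """Batched bilinear logits for stacked mention vectors (P, h) -> (P, 2)."""
        cols = []
        for c in range(2):
            # (P, h) @ (h, h) -> (P, h); row-wise dot with m_j -> (P,)
            cols.append(((m_i @ self.A[c]) * m_j).sum(axis=-1, keepdims=True))
        return _hstack(cols) + self.b


def _hstack(cols: list[Tensor]) -> Tensor:
    """Concatenate (P, 1) tensors along the last axis without a concat op."""
    n = len(cols)
    out = None
    for c, col in enumerate(cols):
        onehot = np.zeros((1, n))
        onehot[0, c] = 1.0
        term = col @ Tensor(onehot)
        out = term if out is None else out + term
    return out


class DocHead:
    """Linear classifier over the classifier-token vector."""

    def __init__(self, task: str, n_classes: int, hidden_size: int, rng: np.random.Generator):
        self.task = task
        self.n_classes = n_classes
        self.W = Tensor.param(rng.normal(0.0, 0.02, size=(n_classes, hidden_size)))
        self.b = Tensor.param(np.zeros(n_classes))

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]

    def logits(self, cls_vec: Tensor) -> Tensor:
        return cls_vec @ self.W.swapaxes(0, 1) + self.b


def cr_probs(V: Tensor, pos_i: int, pos_j: int, cr_head: CRHead) -> Tensor:
    """Coreference probability vector for the mentions whose opening markers
    sit at token positions ``pos_i`` and ``pos_j`` of a single sequence."""
    L = V.shape[0]
    if not (0 <= pos_i < L and 0 <= pos_j < L):
        raise IndexError(f"marker position out of range for sequence length {L}")
    m_i = V[np.array([pos_i])]
    m_j = V[np.array([pos_j])]
    return softmax(cr_head.logits(m_i, m_j), axis=-1).reshape(-1)


def doc_probs(V: Tensor, doc_head: DocHead) -> Tensor:
    """Class probabilities from the classifier-token (row 0) representation."""
    cls_vec = V[np.array([0])].reshape(-1)
    return softmax(doc_head.logits(cls_vec), axis=-1)


def cross_entropy_loss(probs: Tensor, gold: Sequence[int] | int) -> Tensor:
    """Mean negative log-probability of the gold classes.

    ``probs`` is (n,) with an int gold, or (P, n) with a length-P gold
    sequence; the mean is over the P instances.
    """
    if probs.ndim == 1:
        probs = probs.reshape(1, -1)
        gold = [int(gold)]  # type: ignore[list-item]
    gold_idx = np.asarray(gold, dtype=np.intp)
    if gold_idx.size == 0:
        raise ValueError("cross_entropy_loss over an empty instance set")
    rows = np.arange(probs.shape[0])
    picked = probs[(rows, gold_idx)]
    return -(picked.log().mean())


def joint_loss(
    primary_loss: Tensor,
    auxiliary_losses: Mapping[str, Tensor],
    weights: Mapping[str, float],
) -> Tensor:
    """Primary loss plus η-weighted auxiliary losses."""
    total = primary_loss
    for task, loss in auxiliary_losses.items():
        if task not in weights:
            raise KeyError(f"no loss weight for auxiliary task {task!r}")
        total = total + weights[task] * loss
    return total


@dataclass
class ModelBundle:
    """Encoder + the four task heads, with schema and configuration."""

    encoder: TinyTransformerEncoder
    cr_head: CRHead
    doc_heads: dict[str, DocHead]
    schema: LabelSchema
    encoder_config: EncoderConfig
    primary_task: str = "RE"

    @classmethod
    def create(
        cls,
        schema: LabelSchema,
        encoder_config: EncoderConfig,
        primary_task: str = "RE",
        seed: int = 0,
    ) -> "ModelBundle":
        rng = np.random.default_rng(seed)
        h = encoder_config.hidden_size
        encoder = TinyTransformerEncoder(encoder_config, rng)
        heads = {
            "EPT": DocHead("EPT", len(schema.ept_classes), h, rng),
            "RE": DocHead("RE", len(schema.re_classes), h, rng),
            "TNT": DocHead("TNT", len(schema.tnt_classes), h, rng),
        }
        return cls(encoder, CRHead(h, rng), heads, schema, encoder_config, primary_task)

    # -- parameter groups -----------------------------------------------------

    def encoder_parameters(self) -> list[Tensor]:
        return self.encoder.parameters()

    def head_parameters(self) -> list[Tensor]:
        params = list(self.cr_head.parameters())
        for head in self.doc_heads.values():
            params.extend(head.parameters())
        return params

    def parameters(self) -> list[Tensor]:
        return self.encoder_parameters() + self.head_parameters()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- batched forward ------------------------------------------------------

    def pad_batch(self, batch: Sequence[PairSample]) -> tuple[np.ndarray, np.ndarray]:
        L = max(len(s.token_ids) for s in batch)
        ids = np.full((len(batch), L), self.encoder_config.pad_id, dtype=np.intp)
        mask = np.zeros((len(batch), L), dtype=bool)
        for i, s in enumerate(batch):
            ids[i, : len(s.token_ids)] = s.token_ids
            mask[i, : len(s.token_ids)] = True
        return ids, mask

    def forward(self, batch: Sequence[PairSample]) -> Tensor:
        ids, mask = self.pad_batch(batch)
        return self.encoder.encode(ids, mask)

    # -- inference ------------------------------------------------------------

    def predict_re(self, batch: Sequence[PairSample]) -> tuple[list[str], list[float]]:
        """Argmax relation label and its probability per sample."""
        if not batch:
            return [], []
        with no_grad():
            V = self.forward(batch)
            cls_vecs = V[(np.arange(len(batch)), np.zeros(len(batch), dtype=np.intp))]
            probs = softmax(self.doc_heads["RE"].logits(cls_vecs), axis=-1).data
        idx = probs.argmax(axis=-1)
        classes = self.schema.re_classes
        return [classes[i] for i in idx], [float(probs[r, i]) for r, i in enumerate(idx)]

    def predict_tnt(self, batch: Sequence[PairSample]) -> tuple[list[str], list[float]]:
        """Argmax novelty over {Novel, No}; the None column is renormalized
        away at inference."""
        if not batch:
            return [], []
        with no_grad():
            V = self.forward(batch)
            cls_vecs = V[(np.arange(len(batch)), np.zeros(len(batch), dtype=np.intp))]
            probs = softmax(self.doc_heads["TNT"].logits(cls_vecs), axis=-1).data
        classes = self.schema.tnt_classes
        keep = [classes.index(NOVEL), classes.index(NOT_NOVEL)]
        sub = probs[:, keep]
        sub = sub / sub.sum(axis=-1, keepdims=True)
        idx = sub.argmax(axis=-1)
        labels = [NOVEL, NOT_NOVEL]
        return [labels[i] for i in idx], [float(sub[r, i]) for r, i in enumerate(idx)]

    # -- persistence ----------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"encoder.{k}": v for k, v in self.encoder.state_dict().items()}
        state["cr.A"] = self.cr_head.A.data.copy()
        state["cr.b"] = self.cr_head.b.data.copy()
        for task, head in self.doc_heads.items():
            state[f"{task}.W"] = head.W.data.copy()
            state[f"{task}.b"] = head.b.data.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.encoder.load_state_dict(
            {k.removeprefix("encoder."): v for k, v in state.items() if k.startswith("encoder.")}
        )
        self.cr_head.A.data[...] = state["cr.A"]
        self.cr_head.b.data[...] = state["cr.b"]
        for task, head in self.doc_heads.items():
            head.W.data[...] = state[f"{task}.W"]
            head.b.data[...] = state[f"{task}.b"]


def save_bundle(bundle: ModelBundle, path: str) -> None:
    """Write a single-file .npz checkpoint: parameter arrays + JSON metadata
    (label schema, encoder config, primary task)."""
    import json

    meta = {
        "schema": bundle.schema.to_dict(),
        "encoder_config": {
            "vocab": bundle.encoder_config.vocab,
            "max_length": bundle.encoder_config.max_length,
            "hidden_size": bundle.encoder_config.hidden_size,
            "n_layers": bundle.encoder_config.n_layers,
            "n_heads": bundle.encoder_config.n_heads,
            "ffn_size": bundle.encoder_config.ffn_size,
            "open_marker": bundle.encoder_config.open_marker,
            "close_marker": bundle.encoder_config.close_marker,
            "lowercase": bundle.encoder_config.lowercase,
        },
        "primary_task": bundle.primary_task,
    }
    arrays = {k.replace(".", "__"): v for k, v in bundle.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_bundle(path: str) -> ModelBundle:
    """Load a checkpoint written by :func:`save_bundle`."""
    import json

    from .samples import EncoderConfig as _EC

    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"].tobytes()).decode())
        state = {
            k.replace("__", "."): archive[k] for k in archive.files if k != "__meta__"
        }
    schema = LabelSchema.from_dict(meta["schema"])
    enc_cfg = _EC(**meta["encoder_config"])
    bundle = ModelBundle.create(schema, enc_cfg, primary_task=meta["primary_task"])
    bundle.load_state_dict(state)
    return bundle


def batch_task_losses(
    bundle: ModelBundle,
    batch: Sequence[PairSample],
    tnt_uses_none_negatives: bool = True,
) -> dict[str, Tensor]:
    """Per-task cross-entropy losses over one batch of pair samples.

    CR averages over each sample's mention pairs, then over the samples that
    have at least one pair (degenerate samples are excluded from CR but kept
    for the document-level heads).  When ``tnt_uses_none_negatives`` is off,
    no-relation samples are excluded from the TNT loss instead of being
    labeled ``None``.
    """
    schema = bundle.schema
    V = bundle.forward(batch)
    n = len(batch)
    cls_vecs = V[(np.arange(n), np.zeros(n, dtype=np.intp))]
    losses: dict[str, Tensor] = {}

    ept_gold = [schema.ept_index(s.ept_label) for s in batch]
    ept_probs = softmax(bundle.doc_heads["EPT"].logits(cls_vecs), axis=-1)
    losses["EPT"] = cross_entropy_loss(ept_probs, ept_gold)

    re_gold = [schema.re_index(s.re_label) for s in batch]
    re_probs = softmax(bundle.doc_heads["RE"].logits(cls_vecs), axis=-1)
    losses["RE"] = cross_entropy_loss(re_probs, re_gold)

    if tnt_uses_none_negatives:
        tnt_rows = list(range(n))
    else:
        tnt_rows = [i for i, s in enumerate(batch) if s.re_label != NONE_LABEL]
    if tnt_rows:
        tnt_gold = [schema.tnt_index(batch[i].tnt_label) for i in tnt_rows]
        tnt_probs = softmax(
            bundle.doc_heads["TNT"].logits(V[(np.asarray(tnt_rows, dtype=np.intp), np.zeros(len(tnt_rows), dtype=np.intp))]),
            axis=-1,
        )
        losses["TNT"] = cross_entropy_loss(tnt_probs, tnt_gold)

    cr_terms: list[Tensor] = []
    for i, s in enumerate(batch):
        pairs = [
            (a, b, y)
            for a, b, y in s.cr_pairs
            if a in s.open_marker_positions and b in s.open_marker_positions
        ]
        if s.degenerate or not pairs:
            continue
        pi = [s.open_marker_positions[a] for a, _, _ in pairs]
        pj = [s.open_marker_positions[b] for _, b, _ in pairs]
        m_i = gather_rows(V, [i] * len(pairs), pi)
        m_j = gather_rows(V, [i] * len(pairs), pj)
        probs = softmax(bundle.cr_head.logits(m_i, m_j), axis=-1)
        cr_terms.append(cross_entropy_loss(probs, [y for _, _, y in pairs]))
    if cr_terms:
        total = cr_terms[0]
        for t in cr_terms[1:]:
            total = total + t
        losses["CR"] = total * (1.0 / len(cr_terms))
    return losses
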