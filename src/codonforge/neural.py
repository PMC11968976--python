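"""Trainable masked-language-model backend: a numpy transformer encoder.

The architecture follows the BERT-family contract used for codon
prediction: the input embedding is the sum of a token embedding, an
organism token-type embedding, and an absolute positional embedding;
a stack of post-layer-norm self-attention blocks follows; a linear head
maps each position to logits over the 90-token vocabulary. Training
minimizes cross-entropy at the positions selected by the masking
procedure only.

This is a deliberately compact CPU implementation — dense attention,
explicit forward caches and hand-written gradients — sized for corpora
of a few thousand genes. The published full-scale configuration
(12 layers / 12 heads / hidden 768 / intermediate 3072, block-sparse
attention of block size 64, max length 2048) is recorded as a preset;
at these lengths dense attention is exact and the sparse pattern is an
efficiency device, so no sparse kernel is provided.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import erf

from .stream_tokenizer import (
    IGNORE_INDEX,
    EncodedSequence,
    OrganismRegistry,
    Vocabulary,
    apply_mlm_corruption,
)

_LN_EPS = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    """Encoder dimensions. Defaults are the desk-scale configuration."""

    num_layers: int = 2
    num_heads: int = 2
    hidden_size: int = 64
    intermediate_size: int = 128
    attention_block_size: int = 16
    max_len: int = 256
    vocab_size: int = 90
    type_vocab_size: int = 8

    def __post_init__(self) -> None:
        if self.hidden_size % self.num_heads != 0:
            raise ValueError("hidden_size must be divisible by num_heads")
        if self.max_len % self.attention_block_size != 0:
            raise ValueError("max_len must be a multiple of attention_block_size")

    @classmethod
    def published_preset(cls, n_organisms: int) -> "ModelConfig":
        """The full-scale 89.6M-parameter configuration (not used in tests)."""
        return cls(
            num_layers=12,
            num_heads=12,
            hidden_size=768,
            intermediate_size=3072,
            attention_block_size=64,
            max_len=2048,
            vocab_size=90,
            type_vocab_size=n_organisms,
        )


@dataclass(frozen=True)
class TrainSchedule:
    """Batching and the linear warmup / linear decay learning-rate ramp.

    The published run used batch 6, 5 pretraining and 15 fine-tuning
    epochs, ramping 5e-7 -> 5e-5 over the first 10% of steps and back
    down to 5e-7. Desk-scale defaults trade those for a fast CPU fit.
    """

    batch_size: int = 16
    epochs: int = 30
    lr_start: float = 1e-4
    lr_peak: float = 2e-3
    lr_end: float = 1e-4
    warmup_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ValueError("warmup_fraction must be in (0, 1)")
        if min(self.lr_start, self.lr_peak, self.lr_end) <= 0:
            raise ValueError("learning rates must be positive")

    @classmethod
    def published_preset(cls) -> "TrainSchedule":
        return cls(batch_size=6, epochs=5, lr_start=5e-7, lr_peak=5e-5, lr_end=5e-7)

    def learning_rate(self, step: int, total_steps: int) -> float:
        """Piecewise-linear rate at a 0-based optimizer step."""
        warmup = max(1, int(round(self.warmup_fraction * total_steps)))
        if step <= warmup:
            return self.lr_start + (self.lr_peak - self.lr_start) * step / warmup
        remain = max(1, total_steps - warmup)
        t = min(1.0, (step - warmup) / remain)
        return self.lr_peak + (self.lr_end - self.lr_peak) * t


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / math.sqrt(2.0))) + x * np.exp(-0.5 * x * x) / math.sqrt(
        2.0 * math.pi
    )


def _layer_norm_forward(x, gamma, beta):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return xhat * gamma + beta, (xhat, inv, gamma)


def _layer_norm_backward(dy, cache):
    xhat, inv, gamma = cache
    dgamma = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    dbeta = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * gamma
    h = xhat.shape[-1]
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    del h
    return dx, dgamma, dbeta


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class NeuralBackend:
    """Contextual codon predictor over the STREAM vocabulary."""

    def __init__(
        self,
        config: ModelConfig,
        vocab: Vocabulary,
        registry: OrganismRegistry,
        rng: np.random.Generator | None = None,
    ) -> None:
        if config.vocab_size != len(vocab):
            raise ValueError(
                f"config.vocab_size={config.vocab_size} != vocabulary size {len(vocab)}"
            )
        self.config = config
        self.vocab = vocab
        self.registry = registry
        rng = rng if rng is not None else np.random.default_rng(0)
        self.params = self._init_params(rng)

    # ------------------------------------------------------------------
    # parameters

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        c = self.config
        std = 0.02

        def normal(*shape):
            return rng.normal(0.0, std, size=shape)

        p: dict[str, np.ndarray] = {
            "tok_emb": normal(c.vocab_size, c.hidden_size),
            "type_emb": normal(c.type_vocab_size, c.hidden_size),
            "pos_emb": normal(c.max_len, c.hidden_size),
            "ln_emb_g": np.ones(c.hidden_size),
            "ln_emb_b": np.zeros(c.hidden_size),
            "out_w": normal(c.hidden_size, c.vocab_size),
            "out_b": np.zeros(c.vocab_size),
        }
        for i in range(c.num_layers):
            for name in ("q", "k", "v", "o"):
                p[f"l{i}_w{name}"] = normal(c.hidden_size, c.hidden_size)
                p[f"l{i}_b{name}"] = np.zeros(c.hidden_size)
            p[f"l{i}_ln1_g"] = np.ones(c.hidden_size)
            p[f"l{i}_ln1_b"] = np.zeros(c.hidden_size)
            p[f"l{i}_w1"] = normal(c.hidden_size, c.intermediate_size)
            p[f"l{i}_b1"] = np.zeros(c.intermediate_size)
            p[f"l{i}_w2"] = normal(c.intermediate_size, c.hidden_size)
            p[f"l{i}_b2"] = np.zeros(c.hidden_size)
            p[f"l{i}_ln2_g"] = np.ones(c.hidden_size)
            p[f"l{i}_ln2_b"] = np.zeros(c.hidden_size)
        return p

    # ------------------------------------------------------------------
    # forward / backward

    def _forward(self, token_ids, type_ids, attention_mask):
        """Logits (B, L, V) plus the cache needed for the backward pass."""
        p, c = self.params, self.config
        B, L = token_ids.shape
        if L > c.max_len:
            raise ValueError(f"sequence length {L} exceeds max_len {c.max_len}")
        x = p["tok_emb"][token_ids] + p["type_emb"][type_ids] + p["pos_emb"][:L]
        x, ln_emb_cache = _layer_norm_forward(x, p["ln_emb_g"], p["ln_emb_b"])
        # additive attention bias: padded keys get a large negative score
        bias = np.where(attention_mask[:, None, None, :] > 0, 0.0, -1e9)
        nh, dh = c.num_heads, c.hidden_size // c.num_heads
        caches = []
        for i in range(c.num_layers):
            x_in = x
            q = x @ p[f"l{i}_wq"] + p[f"l{i}_bq"]
            k = x @ p[f"l{i}_wk"] + p[f"l{i}_bk"]
            v = x @ p[f"l{i}_wv"] + p[f"l{i}_bv"]
            qh = q.reshape(B, L, nh, dh).transpose(0, 2, 1, 3)
            kh = k.reshape(B, L, nh, dh).transpose(0, 2, 1, 3)
            vh = v.reshape(B, L, nh, dh).transpose(0, 2, 1, 3)
            scores = qh @ kh.transpose(0, 1, 3, 2) / math.sqrt(dh) + bias
            attn = _softmax(scores, axis=-1)
            ctx = (attn @ vh).transpose(0, 2, 1, 3).reshape(B, L, c.hidden_size)
            attn_out = ctx @ p[f"l{i}_wo"] + p[f"l{i}_bo"]
            res1, ln1_cache = _layer_norm_forward(
                x_in + attn_out, p[f"l{i}_ln1_g"], p[f"l{i}_ln1_b"]
            )
            pre = res1 @ p[f"l{i}_w1"] + p[f"l{i}_b1"]
            act = _gelu(pre)
            ffn_out = act @ p[f"l{i}_w2"] + p[f"l{i}_b2"]
            x, ln2_cache = _layer_norm_forward(
                res1 + ffn_out, p[f"l{i}_ln2_g"], p[f"l{i}_ln2_b"]
            )
            caches.append((x_in, qh, kh, vh, attn, ctx, ln1_cache, res1, pre, act, ln2_cache))
        logits = x @ p["out_w"] + p["out_b"]
        cache = (token_ids, type_ids, ln_emb_cache, caches, x, L)
        return logits, cache

    def _backward(self, dlogits, cache):
        p, c = self.params, self.config
        token_ids, type_ids, ln_emb_cache, caches, x_final, L = cache
        B = token_ids.shape[0]
        nh, dh = c.num_heads, c.hidden_size // c.num_heads
        g: dict[str, np.ndarray] = {}
        g["out_w"] = x_final.reshape(-1, c.hidden_size).T @ dlogits.reshape(-1, c.vocab_size)
        g["out_b"] = dlogits.sum(axis=(0, 1))
        dx = dlogits @ p["out_w"].T
        for i in reversed(range(c.num_layers)):
            (x_in, qh, kh, vh, attn, ctx, ln1_cache, res1, pre, act, ln2_cache) = caches[i]
            dsum2, dg, db = _layer_norm_backward(dx, ln2_cache)
            g[f"l{i}_ln2_g"], g[f"l{i}_ln2_b"] = dg, db
            # ffn branch
            dffn = dsum2
            g[f"l{i}_w2"] = act.reshape(-1, c.intermediate_size).T @ dffn.reshape(
                -1, c.hidden_size
            )
            g[f"l{i}_b2"] = dffn.sum(axis=(0, 1))
            dact = dffn @ p[f"l{i}_w2"].T
            dpre = dact * _gelu_grad(pre)
            g[f"l{i}_w1"] = res1.reshape(-1, c.hidden_size).T @ dpre.reshape(
                -1, c.intermediate_size
            )
            g[f"l{i}_b1"] = dpre.sum(axis=(0, 1))
            dres1 = dsum2 + dpre @ p[f"l{i}_w1"].T
            dsum1, dg, db = _layer_norm_backward(dres1, ln1_cache)
            g[f"l{i}_ln1_g"], g[f"l{i}_ln1_b"] = dg, db
            # attention branch
            dattn_out = dsum1
            g[f"l{i}_wo"] = ctx.reshape(-1, c.hidden_size).T @ dattn_out.reshape(
                -1, c.hidden_size
            )
            g[f"l{i}_bo"] = dattn_out.sum(axis=(0, 1))
            dctx = (dattn_out @ p[f"l{i}_wo"].T).reshape(B, L, nh, dh).transpose(0, 2, 1, 3)
            dattn = dctx @ vh.transpose(0, 1, 3, 2)
            dvh = attn.transpose(0, 1, 3, 2) @ dctx
            dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
            dscores /= math.sqrt(dh)
            dqh = dscores @ kh
            dkh = dscores.transpose(0, 1, 3, 2) @ qh
            dq = dqh.transpose(0, 2, 1, 3).reshape(B, L, c.hidden_size)
            dk = dkh.transpose(0, 2, 1, 3).reshape(B, L, c.hidden_size)
            dv = dvh.transpose(0, 2, 1, 3).reshape(B, L, c.hidden_size)
            x_flat = x_in.reshape(-1, c.hidden_size)
            for name, dmat in (("q", dq), ("k", dk), ("v", dv)):
                g[f"l{i}_w{name}"] = x_flat.T @ dmat.reshape(-1, c.hidden_size)
                g[f"l{i}_b{name}"] = dmat.sum(axis=(0, 1))
            dx = (
                dsum1
                + dq @ p[f"l{i}_wq"].T
                + dk @ p[f"l{i}_wk"].T
                + dv @ p[f"l{i}_wv"].T
            )
        demb, dg, db = _layer_norm_backward(dx, ln_emb_cache)
        g["ln_emb_g"], g["ln_emb_b"] = dg, db
        g["tok_emb"] = np.zeros_like(p["tok_emb"])
        np.add.at(g["tok_emb"], token_ids.ravel(), demb.reshape(-1, c.hidden_size))
        g["type_emb"] = np.zeros_like(p["type_emb"])
        np.add.at(g["type_emb"], type_ids.ravel(), demb.reshape(-1, c.hidden_size))
        g["pos_emb"] = np.zeros_like(p["pos_emb"])
        g["pos_emb"][:L] = demb.sum(axis=0)
        return g

    # ------------------------------------------------------------------
    # public API

    def predict_logits_batch(self, token_ids, type_ids, attention_mask) -> np.ndarray:
        logits, _ = self._forward(
            np.asarray(token_ids), np.asarray(type_ids), np.asarray(attention_mask)
        )
        return logits

    def predict_distributions(self, encoded: EncodedSequence) -> np.ndarray:
        """Per-position probability vectors over the vocabulary, shape (L, V)."""
        if int(np.max(encoded.token_type_ids)) >= self.config.type_vocab_size:
            raise ValueError("organism token-type id exceeds type_vocab_size")
        logits = self.predict_logits_batch(
            encoded.token_ids[None, :],
            encoded.token_type_ids[None, :],
            encoded.attention_mask[None, :],
        )[0]
        return _softmax(logits, axis=-1)

    # ------------------------------------------------------------------
    # checkpointing

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(json.dumps(asdict(self.config), indent=1))
        self.vocab.save(directory / "vocab.json")
        self.registry.save(directory / "registry.json")
        np.savez(directory / "weights.npz", **self.params)

    @classmethod
    def load(cls, directory: str | Path) -> "NeuralBackend":
        directory = Path(directory)
        config = ModelConfig(**json.loads((directory / "config.json").read_text()))
        vocab = Vocabulary.load(directory / "vocab.json")
        registry = OrganismRegistry.load(directory / "registry.json")
        backend = cls(config, vocab, registry, rng=np.random.default_rng(0))
        with np.load(directory / "weights.npz") as data:
            backend.params = {k: data[k].copy() for k in data.files}
        return backend


@dataclass
class _AdamState:
    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    t: int = 0


def _adam_step(params, grads, state: _AdamState, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    state.t += 1
    for key, grad in grads.items():
        state.m[key] = beta1 * state.m[key] + (1 - beta1) * grad
        state.v[key] = beta2 * state.v[key] + (1 - beta2) * grad * grad
        mhat = state.m[key] / (1 - beta1**state.t)
        vhat = state.v[key] / (1 - beta2**state.t)
        params[key] -= lr * mhat / (np.sqrt(vhat) + eps)


def masked_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over positions with a real label; also d(loss)/d(logits)."""
    mask = labels != IGNORE_INDEX
    n = int(mask.sum())
    probs = _softmax(logits, axis=-1)
    dlogits = np.zeros_like(logits)
    if n == 0:
        return 0.0, dlogits
    safe_labels = np.where(mask, labels, 0)
    picked = np.take_along_axis(probs, safe_labels[..., None], axis=-1)[..., 0]
    loss = float(-(np.log(np.clip(picked, 1e-12, None)) * mask).sum() / n)
    dlogits = probs.copy()
    np.put_along_axis(
        dlogits,
        safe_labels[..., None],
        np.take_along_axis(dlogits, safe_labels[..., None], axis=-1) - 1.0,
        axis=-1,
    )
    dlogits *= mask[..., None] / n
    return loss, dlogits


def _pad_batch(batch: Sequence[EncodedSequence], pad_id: int):
    L = max(len(e) for e in batch)
    B = len(batch)
    ids = np.full((B, L), pad_id, dtype=np.int64)
    types = np.zeros((B, L), dtype=np.int64)
    mask = np.zeros((B, L), dtype=np.int64)
    labels = np.full((B, L), IGNORE_INDEX, dtype=np.int64)
    for b, enc in enumerate(batch):
        n = len(enc)
        ids[b, :n] = enc.token_ids
        types[b, :n] = enc.token_type_ids
        mask[b, :n] = enc.attention_mask
        if enc.labels is not None:
            labels[b, :n] = enc.labels
    return ids, types, mask, labels


def train_mlm(
    backend: NeuralBackend,
    corpus: Sequence[EncodedSequence],
    schedule: TrainSchedule | None = None,
    seed: int = 0,
    select_rate: float = 0.15,
    mask_frac: float = 0.8,
    random_frac: float = 0.1,
) -> list[float]:
    """Fit the backend by masked-codon prediction; returns per-step losses.

    Each epoch re-corrupts every sequence with fresh randomness, so the
    model sees different masked positions over time. The learning rate
    follows the linear warmup / linear decay ramp of ``schedule``.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    schedule = schedule or TrainSchedule()
    vocab = backend.vocab
    rng = np.random.default_rng(seed)
    # group sequences of similar length to limit padding waste
    order0 = sorted(range(len(corpus)), key=lambda i: len(corpus[i]))
    batches_idx = [
        order0[i : i + schedule.batch_size]
        for i in range(0, len(order0), schedule.batch_size)
    ]
    total_steps = schedule.epochs * len(batches_idx)
    state = _AdamState(
        m={k: np.zeros_like(v) for k, v in backend.params.items()},
        v={k: np.zeros_like(v) for k, v in backend.params.items()},
    )
    losses: list[float] = []
    step = 0
    for _epoch in range(schedule.epochs):
        perm = rng.permutation(len(batches_idx))
        for bi in perm:
            batch = [
                apply_mlm_corruption(
                    vocab,
                    corpus[i],
                    rng,
                    select_rate=select_rate,
                    mask_frac=mask_frac,
                    random_frac=random_frac,
                )
                for i in batches_idx[bi]
            ]
            ids, types, mask, labels = _pad_batch(batch, vocab.pad_id)
            logits, cache = backend._forward(ids, types, mask)
            loss, dlogits = masked_cross_entropy(logits, labels)
            grads = backend._backward(dlogits, cache)
            lr = schedule.learning_rate(step, total_steps)
            _adam_step(backend.params, grads, state, lr)
            losses.append(loss)
            step += 1
    return losses
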