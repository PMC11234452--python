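"""Autoregressive transformer decoder over SMILES tokens.

The architecture follows the small GPT recipe used for molecule
generation: learned token + position embeddings, pre-norm decoder blocks
with causal multi-head self-attention and a GELU feed-forward network,
and a linear vocabulary head.  The full-scale
configuration is 18 layers, 48-dimensional states, 12 attention heads,
512-dimensional feed-forward inner states and a context window of 128
tokens; a 4-layer desk profile is provided for CPU-scale experiments.

Training maximizes the standard language-modeling likelihood
``sum_i log P(u_i | u_{i-k}..u_{i-1}; theta)`` over the concatenated
token stream of the corpus, split into context-window packs.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator

from . import autodiff as ad
from .autodiff import Tensor
from .tokenizer import Vocabulary

_CKPT_VERSION = "gelgen-lm-v1"


@dataclass(frozen=True)
class LMConfig:
    """Hyperparameters of the SMILES language model (full-scale defaults)."""

    n_layers: int = 18
    d_model: int = 48
    n_heads: int = 12
    d_ff: int = 512
    context_window: int = 128
    learning_rate: float = 3e-4
    batch_size: int = 64
    n_epochs: int = 10
    seed: int = 0


#: reduced configuration for CPU-scale runs and tests
DESK_PROFILE = LMConfig(n_layers=4, context_window=64, learning_rate=1e-3)


@dataclass
class TrainingRun:
    """Per-epoch negative log-likelihood record for one training phase."""

    phase: str
    seed: int
    epoch_nll: list = field(default_factory=list)
    val_nll: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return asdict(self)


class SmilesGPT(BaseEstimator):
    """Generative SMILES language model (sklearn-style estimator).

    ``fit`` pretrains on a corpus of SMILES strings; ``finetune`` continues
    training on a second corpus (e.g. known self-assembling molecules)
    without resetting parameters; ``sample`` draws new molecules.

    Fitted attributes: ``vocab_``, ``params_``, ``history_`` (list of
    :class:`TrainingRun`), ``fitted_phase_``.
    """

    def __init__(
        self,
        n_layers: int = 18,
        d_model: int = 48,
        n_heads: int = 12,
        d_ff: int = 512,
        context_window: int = 128,
        learning_rate: float = 3e-4,
        batch_size: int = 64,
        n_epochs: int = 10,
        seed: int = 0,
    ):
        self.n_layers = n_layers
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_ff = d_ff
        self.context_window = context_window
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.seed = seed

    @classmethod
    def from_config(cls, cfg: LMConfig) -> "SmilesGPT":
        return cls(**asdict(cfg))

    # ------------------------------------------------------------------
    # parameters

    def _init_params(self, vocab_size: int) -> dict[str, Tensor]:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.context_window < 2:
            raise ValueError("context window must be at least 2")
        rng = np.random.default_rng(self.seed)
        d, f = self.d_model, self.d_ff

        def w(*shape, std=0.02):
            return Tensor(rng.normal(0.0, std, shape).astype(np.float32))

        p: dict[str, Tensor] = {
            "tok_emb": w(vocab_size, d),
            "pos_emb": w(self.context_window, d),
            # zero head: an untrained model predicts the uniform distribution
            "head_w": Tensor(np.zeros((d, vocab_size), dtype=np.float32)),
            "lnf_g": Tensor(np.ones(d, dtype=np.float32)),
            "lnf_b": Tensor(np.zeros(d, dtype=np.float32)),
        }
        for i in range(self.n_layers):
            p[f"l{i}.ln1_g"] = Tensor(np.ones(d, dtype=np.float32))
            p[f"l{i}.ln1_b"] = Tensor(np.zeros(d, dtype=np.float32))
            p[f"l{i}.ln2_g"] = Tensor(np.ones(d, dtype=np.float32))
            p[f"l{i}.ln2_b"] = Tensor(np.zeros(d, dtype=np.float32))
            for nm in ("wq", "wk", "wv", "wo"):
                p[f"l{i}.{nm}"] = w(d, d)
            p[f"l{i}.bo"] = Tensor(np.zeros(d, dtype=np.float32))
            p[f"l{i}.w1"] = w(d, f)
            p[f"l{i}.b1"] = Tensor(np.zeros(f, dtype=np.float32))
            p[f"l{i}.w2"] = w(f, d)
            p[f"l{i}.b2"] = Tensor(np.zeros(d, dtype=np.float32))
        return p

    # ------------------------------------------------------------------
    # forward

    def _forward(self, ids: np.ndarray) -> Tensor:
        """Logits tensor of shape (B, T, V) for a batch of id arrays."""
        p = self.params_
        B, T = ids.shape
        if T > self.context_window:
            raise ValueError("sequence longer than context window")
        h = self.n_heads
        d = self.d_model
        dh = d // h
        x = ad.add(ad.embedding(p["tok_emb"], ids), ad.embedding(p["pos_emb"], np.arange(T)))
        causal = np.triu(np.full((T, T), -1e9, dtype=np.float32), k=1)
        for i in range(self.n_layers):
            pre = ad.layer_norm(x, p[f"l{i}.ln1_g"], p[f"l{i}.ln1_b"])

            def heads(t):
                return ad.transpose(ad.reshape(t, (B, T, h, dh)), (0, 2, 1, 3))

            q = heads(ad.matmul(pre, p[f"l{i}.wq"]))
            k = heads(ad.matmul(pre, p[f"l{i}.wk"]))
            v = heads(ad.matmul(pre, p[f"l{i}.wv"]))
            scores = ad.scale(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(dh))
            attn = ad.softmax(scores, mask=causal)
            ctx = ad.reshape(ad.transpose(ad.matmul(attn, v), (0, 2, 1, 3)), (B, T, d))
            x = ad.add(x, ad.add(ad.matmul(ctx, p[f"l{i}.wo"]), p[f"l{i}.bo"]))

            pre2 = ad.layer_norm(x, p[f"l{i}.ln2_g"], p[f"l{i}.ln2_b"])
            ff = ad.gelu(ad.add(ad.matmul(pre2, p[f"l{i}.w1"]), p[f"l{i}.b1"]))
            x = ad.add(x, ad.add(ad.matmul(ff, p[f"l{i}.w2"]), p[f"l{i}.b2"]))
        x = ad.layer_norm(x, p["lnf_g"], p["lnf_b"])
        return ad.matmul(x, p["head_w"])

    def sequence_logits(self, ids: list[int] | np.ndarray) -> np.ndarray:
        """Per-position next-token logits (T, V) for one id sequence."""
        self._check_fitted()
        ids = np.asarray(ids, dtype=np.int64)[None, :]
        return self._forward(ids).data[0]

    # ------------------------------------------------------------------
    # data packing

    def _pack(self, smiles: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Concatenate encoded molecules and cut into context-window packs."""
        stream: list[int] = []
        for s in smiles:
            stream.extend(self.vocab_.encode(s))
        stream_arr = np.asarray(stream, dtype=np.int64)
        k = self.context_window
        xs, ys = [], []
        for i in range(0, len(stream_arr) - 1, k):
            inp = stream_arr[i : i + k]
            tgt = stream_arr[i + 1 : i + k + 1]
            if len(inp) < k:
                pad_x = np.full(k - len(inp), self.vocab_.pad_id, dtype=np.int64)
                inp = np.concatenate([inp, pad_x])
            if len(tgt) < k:
                pad_y = np.full(k - len(tgt), -1, dtype=np.int64)
                tgt = np.concatenate([tgt, pad_y])
            xs.append(inp)
            ys.append(tgt)
        return np.stack(xs), np.stack(ys)

    # ------------------------------------------------------------------
    # training

    def fit(
        self,
        X: list[str],
        y=None,
        *,
        vocab: Vocabulary | None = None,
        phase: str = "pretrain",
        validation: list[str] | None = None,
        patience: int | None = None,
        log_file=None,
    ) -> "SmilesGPT":
        """Train on a corpus of SMILES strings.

        ``vocab`` defaults to the vocabulary induced by the corpus.  When
        ``validation`` is given, its NLL is recorded each epoch and, with
        ``patience`` set, training stops after that many epochs without
        improvement.
        """
        X = list(X)
        if not X:
            raise ValueError("empty corpus")
        if not hasattr(self, "params_") or phase == "pretrain":
            self.vocab_ = vocab or Vocabulary.from_corpus(X)
            self.params_ = self._init_params(len(self.vocab_))
            self.history_ = []
            self._opt = ad.Adam(self.params_, lr=self.learning_rate)
        return self._train(X, phase, validation, patience, log_file)

    def finetune(
        self,
        X: list[str],
        *,
        n_epochs: int | None = None,
        learning_rate: float | None = None,
        validation: list[str] | None = None,
        patience: int | None = None,
        log_file=None,
    ) -> "SmilesGPT":
        """Continue training a pretrained model on a new corpus."""
        self._check_fitted()
        saved = (self.n_epochs, self.learning_rate)
        if n_epochs is not None:
            self.n_epochs = n_epochs
        if learning_rate is not None:
            self.learning_rate = learning_rate
            self._opt.lr = learning_rate
        try:
            return self._train(list(X), "finetune", validation, patience, log_file)
        finally:
            self.n_epochs, self.learning_rate = saved

    def _train(self, X, phase, validation, patience, log_file) -> "SmilesGPT":
        xs, ys = self._pack(X)
        run = TrainingRun(phase=phase, seed=self.seed)
        rng = np.random.default_rng(self.seed + 1)
        best, since_best = np.inf, 0
        base_lr = self._opt.lr
        for epoch in range(self.n_epochs):
            # cosine decay to 10% of the base rate over the scheduled epochs
            if self.n_epochs > 1:
                frac = epoch / (self.n_epochs - 1)
                self._opt.lr = base_lr * (0.55 + 0.45 * np.cos(np.pi * frac))
            order = rng.permutation(len(xs))
            losses, weights = [], []
            for b in range(0, len(order), self.batch_size):
                idx = order[b : b + self.batch_size]
                logits = self._forward(xs[idx])
                loss = ad.cross_entropy(logits, ys[idx], ignore_id=-1)
                self._opt.zero_grad()
                loss.backward()
                self._opt.step()
                losses.append(float(loss.data))
                weights.append(int((ys[idx] != -1).sum()))
            nll = float(np.average(losses, weights=weights))
            run.epoch_nll.append(nll)
            msg = f"[{phase}] epoch {epoch + 1}/{self.n_epochs} nll={nll:.4f}"
            if validation is not None:
                vnll = self.nll(validation)
                run.val_nll.append(vnll)
                msg += f" val_nll={vnll:.4f}"
                monitor = vnll
            else:
                monitor = nll
            print(msg, file=sys.stderr)
            if monitor < best - 1e-6:
                best, since_best = monitor, 0
            else:
                since_best += 1
                if patience is not None and since_best >= patience:
                    break
        self._opt.lr = base_lr
        self.history_ = getattr(self, "history_", []) + [run]
        self.fitted_phase_ = phase
        if log_file is not None:
            with open(log_file, "w") as fh:
                json.dump([r.as_dict() for r in self.history_], fh, indent=1)
        return self

    def nll(self, X: list[str]) -> float:
        """Mean per-token negative log-likelihood of a corpus."""
        self._check_fitted()
        xs, ys = self._pack(list(X))
        total, n = 0.0, 0
        for b in range(0, len(xs), self.batch_size):
            logits = self._forward(xs[b : b + self.batch_size])
            loss = ad.cross_entropy(logits, ys[b : b + self.batch_size], ignore_id=-1)
            w = int((ys[b : b + self.batch_size] != -1).sum())
            total += float(loss.data) * w
            n += w
        return total / n

    # ------------------------------------------------------------------
    # sampling (incremental numpy decoder with per-layer KV caches)

    @staticmethod
    def _ln(x: np.ndarray, g: np.ndarray, b: np.ndarray, eps: float = 1e-5) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        return g * (x - mu) / np.sqrt(var + eps) + b

    @staticmethod
    def _gelu_np(x: np.ndarray) -> np.ndarray:
        c = np.sqrt(2.0 / np.pi)
        return 0.5 * x * (1.0 + np.tanh(c * (x + 0.044715 * x**3)))

    def _step_logits(self, tok: np.ndarray, pos: int, kcache, vcache) -> np.ndarray:
        """Next-token logits for one decoding step, extending the KV caches.

        ``tok`` is the (B,) current token; caches are per-layer arrays of
        shape (B, heads, max_len, dh) filled up to ``pos``.
        """
        p = self.params_
        h, d = self.n_heads, self.d_model
        dh = d // h
        B = tok.shape[0]
        x = p["tok_emb"].data[tok] + p["pos_emb"].data[pos]
        for i in range(self.n_layers):
            pre = self._ln(x, p[f"l{i}.ln1_g"].data, p[f"l{i}.ln1_b"].data)
            q = (pre @ p[f"l{i}.wq"].data).reshape(B, h, dh)
            kcache[i][:, :, pos, :] = (pre @ p[f"l{i}.wk"].data).reshape(B, h, dh)
            vcache[i][:, :, pos, :] = (pre @ p[f"l{i}.wv"].data).reshape(B, h, dh)
            K = kcache[i][:, :, : pos + 1, :]
            V = vcache[i][:, :, : pos + 1, :]
            scores = np.einsum("bhd,bhtd->bht", q, K) / np.sqrt(dh)
            scores -= scores.max(axis=-1, keepdims=True)
            w = np.exp(scores)
            w /= w.sum(axis=-1, keepdims=True)
            ctx = np.einsum("bht,bhtd->bhd", w, V).reshape(B, d)
            x = x + ctx @ p[f"l{i}.wo"].data + p[f"l{i}.bo"].data
            pre2 = self._ln(x, p[f"l{i}.ln2_g"].data, p[f"l{i}.ln2_b"].data)
            ff = self._gelu_np(pre2 @ p[f"l{i}.w1"].data + p[f"l{i}.b1"].data)
            x = x + ff @ p[f"l{i}.w2"].data + p[f"l{i}.b2"].data
        x = self._ln(x, p["lnf_g"].data, p["lnf_b"].data)
        return x @ p["head_w"].data

    def sample(
        self,
        n: int,
        temperature: float = 1.0,
        seed: int = 0,
        max_len: int | None = None,
    ) -> list[str]:
        """Draw ``n`` SMILES strings by autoregressive multinomial sampling.

        Generation runs from START until END or ``max_len`` (default: the
        context window).  Deterministic for a given seed.  The returned
        strings are raw model output; validity is judged downstream.
        """
        self._check_fitted()
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        if n == 0:
            return []
        max_len = min(max_len or self.context_window, self.context_window)
        rng = np.random.default_rng(seed)
        v = self.vocab_
        h, dh = self.n_heads, self.d_model // self.n_heads
        kcache = [np.zeros((n, h, max_len, dh), dtype=np.float32) for _ in range(self.n_layers)]
        vcache = [np.zeros((n, h, max_len, dh), dtype=np.float32) for _ in range(self.n_layers)]
        seqs = np.full((n, 1), v.start_id, dtype=np.int64)
        done = np.zeros(n, dtype=bool)
        for pos in range(max_len - 1):
            logits = self._step_logits(seqs[:, -1], pos, kcache, vcache) / temperature
            logits -= logits.max(axis=1, keepdims=True)
            prob = np.exp(logits)
            prob /= prob.sum(axis=1, keepdims=True)
            u = rng.random((n, 1))
            nxt = (prob.cumsum(axis=1) < u).sum(axis=1)
            nxt = np.where(done, v.pad_id, nxt)
            done |= nxt == v.end_id
            seqs = np.concatenate([seqs, nxt[:, None]], axis=1)
            if done.all():
                break
        return [v.decode([i for i in row if i != v.pad_id]) for row in seqs]

    # ------------------------------------------------------------------
    # persistence

    def save(self, path: str) -> None:
        """Write a single-file checkpoint (config + vocabulary + weights)."""
        self._check_fitted()
        meta = {
            "version": _CKPT_VERSION,
            "config": self.get_params(),
            "vocab": list(self.vocab_.tokens),
            "history": [r.as_dict() for r in self.history_],
        }
        arrays = {f"param::{k}": t.data for k, t in self.params_.items()}
        np.savez(path, meta=np.asarray(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str) -> "SmilesGPT":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if meta.get("version") != _CKPT_VERSION:
                raise ValueError(
                    f"checkpoint version mismatch: {meta.get('version')!r}, "
                    f"expected {_CKPT_VERSION!r}"
                )
            model = cls(**meta["config"])
            model.vocab_ = Vocabulary(tuple(meta["vocab"]))
            model.params_ = {
                k[len("param::") :]: Tensor(z[k]) for k in z.files if k.startswith("param::")
            }
        model.history_ = [TrainingRun(**r) for r in meta["history"]]
        model.fitted_phase_ = model.history_[-1].phase if model.history_ else "pretrain"
        model._opt = ad.Adam(model.params_, lr=model.learning_rate)
        return model

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted; call fit() first")
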