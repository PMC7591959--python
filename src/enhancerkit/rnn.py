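"""k-mer tokenization, skip-gram embeddings and an attention LSTM.

The recurrent classification stage: sequences are segmented into
overlapping 3-mers, a skip-gram word2vec model learns a dense vector per
token, and a two-layer LSTM (hidden size 100) with additive attention
pooling and a sigmoid head predicts the binary class, trained with Adam at
learning rate 0.005. The network — forward pass, backpropagation through
time and the Adam updates — is implemented directly on numpy arrays; a
numerical gradient check in the test suite guards the analytic gradients.

Attention is additive with a single learned context vector:

    u_t = tanh(W_a h_t + b_a),  e_t = v . u_t,  alpha = softmax(e),
    context = sum_t alpha_t h_t,

so the per-time-step weights alpha are non-negative and sum to one for
every sequence, and can be read back from the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classify import Prediction
from .io import SequenceRecord

_NT = "ACGT"

UNK = "<unk>"


class DivergenceError(RuntimeError):
    """Raised when training loss becomes non-finite."""


@dataclass(frozen=True)
class TokenSequence:
    """Ordered k-mer tokens for one record."""

    record_id: str
    tokens: tuple[str, ...]


def tokenize(
    records: Iterable[SequenceRecord], k: int = 3, stride: int = 1
) -> list[TokenSequence]:
    """Segment each sequence into k-mer tokens, 5'->3'."""
    if k < 1 or stride < 1:
        raise ValueError("k and stride must be positive")
    out = []
    for r in records:
        if len(r) < k:
            raise ValueError(f"record {r.id!r}: length {len(r)} < k={k}")
        toks = tuple(r.seq[i : i + k] for i in range(0, len(r) - k + 1, stride))
        out.append(TokenSequence(r.id, toks))
    return out


def detokenize(tokens: Sequence[str], stride: int = 1) -> str:
    """Reconstruct the sequence from stride-1 (or non-overlapping) tokens."""
    if not tokens:
        raise ValueError("no tokens")
    k = len(tokens[0])
    if stride >= k:
        return "".join(tokens)
    return tokens[0] + "".join(t[-stride:] for t in tokens[1:])


def vocabulary(k: int = 3) -> list[str]:
    """All 4**k k-mers plus the reserved unknown token (last index)."""
    return ["".join(p) for p in product(_NT, repeat=k)] + [UNK]


def token_ids(
    sequences: Sequence[TokenSequence], vocab: Sequence[str]
) -> np.ndarray:
    """(n, T) integer id matrix; unknown tokens map to the <unk> index.

    All sequences must have the same token count.
    """
    lengths = {len(s.tokens) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"token counts differ across sequences: {sorted(lengths)}")
    index = {t: i for i, t in enumerate(vocab)}
    unk = index[UNK]
    return np.array(
        [[index.get(t, unk) for t in s.tokens] for s in sequences], dtype=np.int64
    )


# ---------------------------------------------------------------------------
# word2vec (skip-gram with full softmax; the vocabulary is tiny)


def train_embeddings(
    token_sequences: Sequence[TokenSequence],
    embedding_dim: int = 100,
    window: int = 5,
    epochs: int = 3,
    learning_rate: float = 0.05,
    seed: int = 0,
    k: int = 3,
) -> dict[str, np.ndarray]:
    """Skip-gram token embeddings trained by minibatch SGD.

    Every k-mer of the vocabulary is present in the returned map (tokens
    never seen in the corpus keep their random initialization), plus the
    reserved unknown token.
    """
    if not token_sequences:
        raise ValueError("empty corpus")
    vocab = vocabulary(k)
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)
    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, embedding_dim)) - 0.5) / embedding_dim
    W_out = np.zeros((V, embedding_dim))

    centers, contexts = [], []
    for s in token_sequences:
        ids = [index.get(t, V - 1) for t in s.tokens]
        for i, c in enumerate(ids):
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    centers = np.array(centers, dtype=np.int64)
    contexts = np.array(contexts, dtype=np.int64)

    batch = 512
    for _ in range(epochs):
        perm = rng.permutation(centers.size)
        for s0 in range(0, centers.size, batch):
            sel = perm[s0 : s0 + batch]
            c, t = centers[sel], contexts[sel]
            h = W_in[c]  # (b, d)
            logits = h @ W_out.T  # (b, V)
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(sel.size), t] -= 1.0  # dL/dlogits
            p /= sel.size
            grad_h = p @ W_out
            W_out -= learning_rate * (p.T @ h)
            np.add.at(W_in, c, -learning_rate * grad_h)
    return {tok: W_in[i].copy() for tok, i in index.items()}


# ---------------------------------------------------------------------------
# attention LSTM


@dataclass
class RnnConfig:
    """Hyperparameters of the recurrent stage (defaults: two layers of
    hidden size 100, learning rate 0.005, Adam)."""

    layers: int = 2
    hidden_dim: int = 100
    learning_rate: float = 0.005
    optimizer: str = "adam"
    embedding_dim: int = 100
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    k: int = 3

    def __post_init__(self) -> None:
        if min(self.layers, self.hidden_dim, self.embedding_dim, self.epochs, self.batch_size) < 1:
            raise ValueError("layers, dims, epochs and batch size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class AttentionLSTM:
    """Two-layer LSTM with additive attention pooling and a sigmoid head.

    Parameters live in a flat dict so the analytic gradients can be
    checked numerically; ``fit`` consumes an (n, T) token-id matrix.
    """

    def __init__(self, config: RnnConfig, vocab: Sequence[str] | None = None):
        self.config = config
        self.vocab = list(vocab) if vocab is not None else vocabulary(config.k)
        self.params: dict[str, np.ndarray] = {}
        self._adam_m: dict[str, np.ndarray] = {}
        self._adam_v: dict[str, np.ndarray] = {}
        self._adam_t = 0
        self.history: list[dict[str, float]] = []
        self._init_params()

    # -- initialization -----------------------------------------------------

    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        V, D, H = len(self.vocab), cfg.embedding_dim, cfg.hidden_dim
        p: dict[str, np.ndarray] = {}
        p["E"] = (rng.random((V, D)) - 0.5) / np.sqrt(D)
        for l in range(cfg.layers):
            d_in = D if l == 0 else H
            s_x, s_h = 1.0 / np.sqrt(d_in), 1.0 / np.sqrt(H)
            p[f"Wx{l}"] = rng.uniform(-s_x, s_x, (d_in, 4 * H))
            p[f"Wh{l}"] = rng.uniform(-s_h, s_h, (H, 4 * H))
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias
            p[f"b{l}"] = b
        s = 1.0 / np.sqrt(H)
        p["Wa"] = rng.uniform(-s, s, (H, H))
        p["ba"] = np.zeros(H)
        p["v"] = rng.uniform(-s, s, H)
        p["wo"] = rng.uniform(-s, s, H)
        p["bo"] = np.zeros(1)
        self.params = p

    def load_embeddings(self, emb: Mapping[str, np.ndarray]) -> None:
        """Initialize the embedding layer from a trained token->vector map."""
        E = self.params["E"]
        for i, tok in enumerate(self.vocab):
            if tok in emb:
                vec = np.asarray(emb[tok], dtype=float)
                if vec.shape != (E.shape[1],):
                    raise ValueError(
                        f"embedding for {tok!r} has dim {vec.shape}, expected {E.shape[1]}"
                    )
                E[i] = vec

    # -- forward ------------------------------------------------------------

    def _forward(self, ids: np.ndarray):
        """Forward pass; returns probabilities, attention and caches."""
        p = self.params
        cfg = self.config
        B, T = ids.shape
        H = cfg.hidden_dim
        x = p["E"][ids]  # (B, T, D)
        caches = []
        layer_in = x
        for l in range(cfg.layers):
            Wx, Wh, b = p[f"Wx{l}"], p[f"Wh{l}"], p[f"b{l}"]
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            hs = np.zeros((B, T, H))
            gates = np.zeros((B, T, 4 * H))
            cs = np.zeros((B, T, H))
            for t in range(T):
                z = layer_in[:, t] @ Wx + h @ Wh + b
                i_g = _sigmoid(z[:, :H])
                f_g = _sigmoid(z[:, H : 2 * H])
                g_g = np.tanh(z[:, 2 * H : 3 * H])
                o_g = _sigmoid(z[:, 3 * H :])
                c = f_g * c + i_g * g_g
                h = o_g * np.tanh(c)
                hs[:, t] = h
                cs[:, t] = c
                gates[:, t, :H] = i_g
                gates[:, t, H : 2 * H] = f_g
                gates[:, t, 2 * H : 3 * H] = g_g
                gates[:, t, 3 * H :] = o_g
            caches.append({"in": layer_in, "hs": hs, "cs": cs, "gates": gates})
            layer_in = hs
        hs_top = layer_in  # (B, T, H)
        u = np.tanh(hs_top @ p["Wa"] + p["ba"])  # (B, T, H)
        e = u @ p["v"]  # (B, T)
        e = e - e.max(axis=1, keepdims=True)
        alpha = np.exp(e)
        alpha /= alpha.sum(axis=1, keepdims=True)
        ctx = np.einsum("bt,bth->bh", alpha, hs_top)
        logit = ctx @ p["wo"] + p["bo"][0]
        prob = _sigmoid(logit)
        attn_cache = {"u": u, "alpha": alpha, "ctx": ctx, "hs_top": hs_top}
        return prob, alpha, caches, attn_cache, ids

    def _loss_and_grads(self, ids: np.ndarray, y: np.ndarray):
        """Mean binary cross-entropy and gradients for every parameter."""
        p = self.params
        cfg = self.config
        B, T = ids.shape
        H = cfg.hidden_dim
        prob, alpha, caches, att, _ = self._forward(ids)
        eps = 1e-12
        loss = -np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogit = (prob - y) / B  # (B,)
        grads["wo"] = att["ctx"].T @ dlogit
        grads["bo"] = np.array([dlogit.sum()])
        dctx = dlogit[:, None] * p["wo"][None, :]  # (B, H)
        hs_top = att["hs_top"]
        dalpha = np.einsum("bh,bth->bt", dctx, hs_top)
        dhs_top = alpha[:, :, None] * dctx[:, None, :]
        # softmax backward
        de = alpha * (dalpha - (dalpha * alpha).sum(axis=1, keepdims=True))
        u = att["u"]
        du = de[:, :, None] * p["v"][None, None, :]
        da_u = du * (1.0 - u * u)
        grads["v"] = (u * de[:, :, None]).sum(axis=(0, 1))
        grads["Wa"] = np.einsum("bth,bta->ha", hs_top, da_u)
        grads["ba"] = da_u.sum(axis=(0, 1))
        dhs_top = dhs_top + da_u @ p["Wa"].T

        d_layer_out = dhs_top
        for l in reversed(range(cfg.layers)):
            cache = caches[l]
            Wx, Wh = p[f"Wx{l}"], p[f"Wh{l}"]
            hs, cs, gates, layer_in = cache["hs"], cache["cs"], cache["gates"], cache["in"]
            dWx = np.zeros_like(Wx)
            dWh = np.zeros_like(Wh)
            db = np.zeros(4 * H)
            d_in = np.zeros_like(layer_in)
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in reversed(range(T)):
                i_g = gates[:, t, :H]
                f_g = gates[:, t, H : 2 * H]
                g_g = gates[:, t, 2 * H : 3 * H]
                o_g = gates[:, t, 3 * H :]
                c_t = cs[:, t]
                c_prev = cs[:, t - 1] if t > 0 else np.zeros((B, H))
                h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H))
                tanh_c = np.tanh(c_t)
                dh = d_layer_out[:, t] + dh_next
                dc = dc_next + dh * o_g * (1.0 - tanh_c * tanh_c)
                da = np.empty((B, 4 * H))
                da[:, :H] = dc * g_g * i_g * (1 - i_g)
                da[:, H : 2 * H] = dc * c_prev * f_g * (1 - f_g)
                da[:, 2 * H : 3 * H] = dc * i_g * (1.0 - g_g * g_g)
                da[:, 3 * H :] = dh * tanh_c * o_g * (1 - o_g)
                dWx += layer_in[:, t].T @ da
                dWh += h_prev.T @ da
                db += da.sum(axis=0)
                d_in[:, t] = da @ Wx.T
                dh_next = da @ Wh.T
                dc_next = dc * f_g
            grads[f"Wx{l}"] = dWx
            grads[f"Wh{l}"] = dWh
            grads[f"b{l}"] = db
            d_layer_out = d_in
        np.add.at(grads["E"], ids, d_layer_out)
        return loss, grads

    # -- training -----------------------------------------------------------

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        lr = self.config.learning_rate
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m.setdefault(k, np.zeros_like(g))
            v = self._adam_v.setdefault(k, np.zeros_like(g))
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            m_hat = m / (1 - b1**t)
            v_hat = v / (1 - b2**t)
            self.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def fit(self, ids: np.ndarray, labels: Sequence[int]) -> "AttentionLSTM":
        """Train on an (n, T) token-id matrix with binary labels."""
        cfg = self.config
        ids = np.asarray(ids, dtype=np.int64)
        y = np.asarray(labels, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary")
        rng = np.random.default_rng(cfg.seed)
        n = ids.shape[0]
        for epoch in range(1, cfg.epochs + 1):
            perm = rng.permutation(n)
            total = 0.0
            for s0 in range(0, n, cfg.batch_size):
                sel = perm[s0 : s0 + cfg.batch_size]
                loss, grads = self._loss_and_grads(ids[sel], y[sel])
                if not np.isfinite(loss):
                    raise DivergenceError(f"non-finite loss at epoch {epoch}")
                self._adam_step(grads)
                total += loss * sel.size
            probs = self.predict_proba(ids)
            acc = float(np.mean((probs >= 0.5) == (y == 1)))
            self.history.append(
                {"epoch": epoch, "loss": total / n, "train_accuracy": acc}
            )
        return self

    # -- inference ----------------------------------------------------------

    def predict_proba(self, ids: np.ndarray, batch: int = 256) -> np.ndarray:
        ids = np.asarray(ids, dtype=np.int64)
        out = np.empty(ids.shape[0])
        for s0 in range(0, ids.shape[0], batch):
            prob, _, _, _, _ = self._forward(ids[s0 : s0 + batch])
            out[s0 : s0 + batch] = prob
        return out

    def attention_weights(self, ids: np.ndarray) -> np.ndarray:
        """Per-time-step attention weights (rows sum to 1)."""
        _, alpha, _, _, _ = self._forward(np.asarray(ids, dtype=np.int64))
        return alpha


def train_attention_lstm(
    token_sequences: Sequence[TokenSequence],
    labels: Mapping[str, int] | Sequence[int],
    embeddings: Mapping[str, np.ndarray] | None = None,
    config: RnnConfig | None = None,
) -> AttentionLSTM:
    """Fit the attention LSTM on tokenized sequences.

    ``labels`` is either a record_id -> {0,1} map or a parallel sequence.
    """
    if not token_sequences:
        raise ValueError("no sequences")
    config = config or RnnConfig()
    if isinstance(labels, Mapping):
        y = [labels[s.record_id] for s in token_sequences]
    else:
        y = list(labels)
    model = AttentionLSTM(config)
    if embeddings is not None:
        model.load_embeddings(embeddings)
    ids = token_ids(token_sequences, model.vocab)
    return model.fit(ids, y)


def predict(
    model: AttentionLSTM, token_sequences: Sequence[TokenSequence]
) -> list[Prediction]:
    """Per-sequence label with confidence = max(p, 1-p)."""
    if not token_sequences:
        raise ValueError("no sequences to predict")
    ids = token_ids(token_sequences, model.vocab)
    probs = model.predict_proba(ids)
    return [
        Prediction(
            s.record_id,
            int(p >= 0.5),
            float(max(p, 1.0 - p)),
            "attention-lstm",
        )
        for s, p in zip(token_sequences, probs)
    ]
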