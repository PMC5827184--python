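"""From-scratch prediction networks: SRN, LSTM, and Skip-gram.

All three learners share the same localist input scheme: a word is a
one-of-V vector that carries no similarity information, so any structure
in the learned representations is earned from the word-order statistics
of the corpus alone.  The recurrent models (SRN, gated LSTM) predict the
next word from a 7-token window — the current word and the six words
immediately to its left — with the hidden state reset at the start of
every window and the cross-entropy error taken at the final step only
(one prediction error per corpus word).  Skip-gram predicts context words
from the center word within a symmetric window and is trained with the
negative-sampling objective.

Everything is plain NumPy.  Per-window operations (`window_loss`,
`backprop_window`, `srn_step`, `lstm_step`) exist for inspection and for
finite-difference gradient checking; the training loop uses the batched
equivalents in this module, which compute identical quantities over a
stack of windows at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .corpus import InvalidConfigError

#: Window length: the current word plus six predecessors.
WINDOW_LENGTH = 7


# ---------------------------------------------------------------------------
# initialization


@dataclass
class InitSpec:
    """Truncated-normal initialization: mean 0, sd 1/m with m the number of
    units in the layer above, truncated at ±2 sd; output bias zero."""

    truncation_sds: float = 2.0
    seed: int = 0


def truncated_normal(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    sd: float,
    truncation_sds: float = 2.0,
) -> np.ndarray:
    """Normal(0, sd) draws redrawn until they fall inside ±truncation·sd."""
    out = rng.normal(0.0, sd, size=shape)
    bound = truncation_sds * sd
    bad = np.abs(out) > bound
    while bad.any():
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) > bound
    return out


@dataclass
class SRNWeights:
    """Input→hidden, recurrent, and hidden→output matrices plus output bias."""

    w_in: np.ndarray  # (V, H): one-hot input -> row lookup
    w_rec: np.ndarray  # (H, H)
    w_out: np.ndarray  # (H, V)
    b_out: np.ndarray  # (V,)

    @property
    def n_symbols(self) -> int:
        return self.w_in.shape[0]

    @property
    def hidden_size(self) -> int:
        return self.w_in.shape[1]

    def params(self) -> dict[str, np.ndarray]:
        return {"w_in": self.w_in, "w_rec": self.w_rec,
                "w_out": self.w_out, "b_out": self.b_out}


@dataclass
class LSTMWeights:
    """Gated recurrent unit bank: input/forget/output gates plus candidate.

    Gate pre-activations are affine in [current input, previous output];
    the four gate blocks are stored stacked side by side in the order
    (input, forget, output, candidate), so ``w_x`` is (V, 4H), ``w_h`` is
    (H, 4H) and ``b`` is (4H,).
    """

    w_x: np.ndarray  # (V, 4H)
    w_h: np.ndarray  # (H, 4H)
    b: np.ndarray  # (4H,)
    w_out: np.ndarray  # (H, V)
    b_out: np.ndarray  # (V,)

    @property
    def n_symbols(self) -> int:
        return self.w_x.shape[0]

    @property
    def hidden_size(self) -> int:
        return self.w_h.shape[0]

    def params(self) -> dict[str, np.ndarray]:
        return {"w_x": self.w_x, "w_h": self.w_h, "b": self.b,
                "w_out": self.w_out, "b_out": self.b_out}


@dataclass
class SkipGramWeights:
    """Input and output embedding tables of a Skip-gram model."""

    w_in: np.ndarray  # (V, H) input embeddings = the word representations
    w_out: np.ndarray  # (V, H) output (context) embeddings
    window_size: int = 3
    n_epochs: int = 20

    @property
    def n_symbols(self) -> int:
        return self.w_in.shape[0]

    @property
    def hidden_size(self) -> int:
        return self.w_in.shape[1]

    def params(self) -> dict[str, np.ndarray]:
        return {"w_in": self.w_in, "w_out": self.w_out}


ModelWeights = SRNWeights | LSTMWeights | SkipGramWeights


def init_weights(
    spec: InitSpec,
    arch: str,
    n_symbols: int,
    hidden_size: int,
    **arch_kwargs,
) -> ModelWeights:
    """Initialize a model of the given architecture ('srn'|'lstm'|'skipgram').

    Every matrix gets truncated-normal draws with sd equal to 1 over the
    number of units in the layer above it (hidden matrices: 1/H; matrices
    feeding the output layer: 1/V); all biases start at zero.
    """
    rng = np.random.default_rng(spec.seed)
    v, h = n_symbols, hidden_size
    t = spec.truncation_sds
    if arch == "srn":
        return SRNWeights(
            w_in=truncated_normal(rng, (v, h), 1.0 / h, t),
            w_rec=truncated_normal(rng, (h, h), 1.0 / h, t),
            w_out=truncated_normal(rng, (h, v), 1.0 / v, t),
            b_out=np.zeros(v),
        )
    if arch == "lstm":
        return LSTMWeights(
            w_x=truncated_normal(rng, (v, 4 * h), 1.0 / h, t),
            w_h=truncated_normal(rng, (h, 4 * h), 1.0 / h, t),
            b=np.zeros(4 * h),
            w_out=truncated_normal(rng, (h, v), 1.0 / v, t),
            b_out=np.zeros(v),
        )
    if arch == "skipgram":
        return SkipGramWeights(
            w_in=truncated_normal(rng, (v, h), 1.0 / h, t),
            w_out=truncated_normal(rng, (v, h), 1.0 / v, t),
            **arch_kwargs,
        )
    raise InvalidConfigError(f"unknown architecture {arch!r}")


# ---------------------------------------------------------------------------
# single-step recurrences (reference implementations)


def _check_tokens(weights: ModelWeights, token_ids: np.ndarray) -> None:
    token_ids = np.asarray(token_ids)
    if token_ids.size and (
        token_ids.min() < 0 or token_ids.max() >= weights.n_symbols
    ):
        raise ValueError("token id out of vocabulary range")


def srn_step(weights: SRNWeights, token_id: int, h_prev: np.ndarray) -> np.ndarray:
    """h = tanh(W_in·onehot(token) + W_rec·h_prev); components in (-1, 1)."""
    _check_tokens(weights, np.asarray([token_id]))
    return np.tanh(weights.w_in[token_id] + h_prev @ weights.w_rec)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def lstm_step(
    weights: LSTMWeights,
    token_id: int,
    state_prev: tuple[np.ndarray, np.ndarray],
    forced_gates: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One gated update: returns (cell, output).

    cell = forget ⊙ cell_prev + input ⊙ tanh(candidate);
    output = output_gate ⊙ tanh(cell).  ``forced_gates`` clamps named
    gates ('input'|'forget'|'output') to a constant, for probing the
    gating semantics (e.g. forget=0 flushes the memory cell).
    """
    _check_tokens(weights, np.asarray([token_id]))
    c_prev, h_prev = state_prev
    hsize = weights.hidden_size
    z = weights.w_x[token_id] + h_prev @ weights.w_h + weights.b
    i = _sigmoid(z[:hsize])
    f = _sigmoid(z[hsize:2 * hsize])
    o = _sigmoid(z[2 * hsize:3 * hsize])
    g = np.tanh(z[3 * hsize:])
    if forced_gates:
        i = np.full(hsize, forced_gates["input"]) if "input" in forced_gates else i
        f = np.full(hsize, forced_gates["forget"]) if "forget" in forced_gates else f
        o = np.full(hsize, forced_gates["output"]) if "output" in forced_gates else o
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return c, h


def output_distribution(weights: ModelWeights, hidden: np.ndarray) -> np.ndarray:
    """Softmax over the vocabulary with max-subtraction stabilization."""
    logits = hidden @ weights.w_out + weights.b_out
    return softmax(logits)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# windows


@dataclass
class ContextWindow:
    """Up to 7 token ids (current word and six predecessors) plus the
    following token as prediction target."""

    tokens: np.ndarray
    target: int

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens, dtype=np.int64)
        if not 1 <= self.tokens.shape[0] <= WINDOW_LENGTH:
            raise ValueError("window must hold 1..7 tokens")


def make_windows(
    tokens: np.ndarray, pad_id: int, length: int = WINDOW_LENGTH
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding 7-token windows over a stream; every token is a target.

    The window for the target at position t holds tokens t-7..t-1, with
    stream-initial positions left-padded by the reserved boundary symbol
    ``pad_id``.  Returns (windows (N, length), targets (N,)).
    """
    tokens = np.asarray(tokens, dtype=np.int64)
    n = tokens.shape[0]
    padded = np.concatenate([np.full(length, pad_id, dtype=np.int64), tokens])
    idx = np.arange(length)[None, :] + np.arange(n)[:, None]
    return padded[idx], tokens


def make_anchor_windows(
    tokens: np.ndarray, pad_id: int, length: int = WINDOW_LENGTH
) -> np.ndarray:
    """One window per stream position, *ending* in that position's token.

    Used for representation extraction: the hidden state at the end of
    the window anchored at position p is the state that encodes token p
    in its left context (it equals the state used to predict token p+1).
    """
    tokens = np.asarray(tokens, dtype=np.int64)
    n = tokens.shape[0]
    padded = np.concatenate(
        [np.full(length - 1, pad_id, dtype=np.int64), tokens]
    )
    idx = np.arange(length)[None, :] + np.arange(n)[:, None]
    return padded[idx]


# ---------------------------------------------------------------------------
# batched forward / backward


def forward_srn(
    weights: SRNWeights, windows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Run the SRN over a (B, T) window stack from reset state.

    Returns (hs, probs): hs has shape (T+1, B, H) with hs[0] the zero
    state, probs the softmax output at the final step.
    """
    _check_tokens(weights, windows)
    b, t = windows.shape
    h = weights.hidden_size
    hs = np.zeros((t + 1, b, h))
    for step in range(t):
        hs[step + 1] = np.tanh(
            weights.w_in[windows[:, step]] + hs[step] @ weights.w_rec
        )
    probs = softmax(hs[t] @ weights.w_out + weights.b_out)
    return hs, probs


def backward_srn(
    weights: SRNWeights,
    windows: np.ndarray,
    targets: np.ndarray,
    hs: np.ndarray,
    probs: np.ndarray,
) -> dict[str, np.ndarray]:
    """Truncated-BPTT gradients of the mean final-step cross-entropy."""
    b, t = windows.shape
    d = probs.copy()
    d[np.arange(b), targets] -= 1.0
    d /= b
    grads = {
        "w_out": hs[t].reshape(b, -1).T @ d,
        "b_out": d.sum(axis=0),
        "w_in": np.zeros_like(weights.w_in),
        "w_rec": np.zeros_like(weights.w_rec),
    }
    dh = d @ weights.w_out.T
    for step in range(t - 1, -1, -1):
        da = dh * (1.0 - hs[step + 1] ** 2)
        np.add.at(grads["w_in"], windows[:, step], da)
        grads["w_rec"] += hs[step].T @ da
        dh = da @ weights.w_rec.T
    return grads


def forward_lstm(
    weights: LSTMWeights, windows: np.ndarray
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Run the LSTM over a (B, T) window stack from reset state.

    Returns (cache, probs); cache holds per-step gate activations and
    states needed for the backward pass, with cache["h"][-1] the final
    gated output fed to the softmax layer.
    """
    _check_tokens(weights, windows)
    b, t = windows.shape
    h = weights.hidden_size
    cache = {
        "i": np.zeros((t, b, h)), "f": np.zeros((t, b, h)),
        "o": np.zeros((t, b, h)), "g": np.zeros((t, b, h)),
        "c": np.zeros((t + 1, b, h)), "h": np.zeros((t + 1, b, h)),
        "tanh_c": np.zeros((t, b, h)),
    }
    for step in range(t):
        z = (
            weights.w_x[windows[:, step]]
            + cache["h"][step] @ weights.w_h
            + weights.b
        )
        i = _sigmoid(z[:, :h])
        f = _sigmoid(z[:, h:2 * h])
        o = _sigmoid(z[:, 2 * h:3 * h])
        g = np.tanh(z[:, 3 * h:])
        c = f * cache["c"][step] + i * g
        tc = np.tanh(c)
        cache["i"][step], cache["f"][step] = i, f
        cache["o"][step], cache["g"][step] = o, g
        cache["c"][step + 1] = c
        cache["tanh_c"][step] = tc
        cache["h"][step + 1] = o * tc
    probs = softmax(cache["h"][t] @ weights.w_out + weights.b_out)
    return cache, probs


def backward_lstm(
    weights: LSTMWeights,
    windows: np.ndarray,
    targets: np.ndarray,
    cache: dict[str, np.ndarray],
    probs: np.ndarray,
) -> dict[str, np.ndarray]:
    """Truncated-BPTT gradients of the mean final-step cross-entropy."""
    b, t = windows.shape
    h = weights.hidden_size
    d = probs.copy()
    d[np.arange(b), targets] -= 1.0
    d /= b
    grads = {
        "w_out": cache["h"][t].T @ d,
        "b_out": d.sum(axis=0),
        "w_x": np.zeros_like(weights.w_x),
        "w_h": np.zeros_like(weights.w_h),
        "b": np.zeros_like(weights.b),
    }
    dh = d @ weights.w_out.T
    dc = np.zeros((b, h))
    for step in range(t - 1, -1, -1):
        i, f = cache["i"][step], cache["f"][step]
        o, g = cache["o"][step], cache["g"][step]
        tc = cache["tanh_c"][step]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc ** 2)
        di = dc * g
        df = dc * cache["c"][step]
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                do * o * (1.0 - o),
                dg * (1.0 - g ** 2),
            ],
            axis=1,
        )
        np.add.at(grads["w_x"], windows[:, step], dz)
        grads["w_h"] += cache["h"][step].T @ dz
        grads["b"] += dz.sum(axis=0)
        dh = dz @ weights.w_h.T
        dc = dc * f
    return grads


def _as_batch(window: ContextWindow) -> tuple[np.ndarray, np.ndarray]:
    return window.tokens[None, :], np.asarray([window.target])


def window_loss(
    weights: SRNWeights | LSTMWeights, window: ContextWindow
) -> tuple[float, dict]:
    """Negative log probability of the target at the window's final step.

    The recurrence runs from a reset state across the window; the loss is
    taken at the last step only (one prediction error per word).  Returns
    the loss and the cached activations for the backward pass.
    """
    tokens, targets = _as_batch(window)
    if isinstance(weights, SRNWeights):
        hs, probs = forward_srn(weights, tokens)
        cache = {"hs": hs, "probs": probs}
    else:
        lstm_cache, probs = forward_lstm(weights, tokens)
        cache = {"lstm": lstm_cache, "probs": probs}
    loss = float(-np.log(probs[0, window.target]))
    return loss, cache


def backprop_window(
    weights: SRNWeights | LSTMWeights,
    window: ContextWindow,
    cache: dict | None = None,
) -> dict[str, np.ndarray]:
    """Gradients of `window_loss` w.r.t. every weight array (BPTT ≤ 7 steps)."""
    tokens, targets = _as_batch(window)
    if cache is None:
        _, cache = window_loss(weights, window)
    if isinstance(weights, SRNWeights):
        return backward_srn(weights, tokens, targets, cache["hs"], cache["probs"])
    return backward_lstm(weights, tokens, targets, cache["lstm"], cache["probs"])


def batch_loss_and_grads(
    weights: SRNWeights | LSTMWeights,
    windows: np.ndarray,
    targets: np.ndarray,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean final-step cross-entropy over a window stack, with gradients."""
    if isinstance(weights, SRNWeights):
        hs, probs = forward_srn(weights, windows)
        grads = backward_srn(weights, windows, targets, hs, probs)
    else:
        cache, probs = forward_lstm(weights, windows)
        grads = backward_lstm(weights, windows, targets, cache, probs)
    nll = -np.log(probs[np.arange(windows.shape[0]), targets])
    return float(nll.mean()), grads


def final_hidden_states(
    weights: SRNWeights | LSTMWeights, windows: np.ndarray
) -> np.ndarray:
    """Hidden state at the last step of each window (no weight updates)."""
    if isinstance(weights, SRNWeights):
        hs, _ = forward_srn(weights, windows)
        return hs[-1]
    cache, _ = forward_lstm(weights, windows)
    return cache["h"][-1]


def window_nll(
    weights: SRNWeights | LSTMWeights,
    windows: np.ndarray,
    targets: np.ndarray,
) -> np.ndarray:
    """Per-window negative log probability of the target (natural log)."""
    if isinstance(weights, SRNWeights):
        _, probs = forward_srn(weights, windows)
    else:
        _, probs = forward_lstm(weights, windows)
    return -np.log(probs[np.arange(windows.shape[0]), targets])


# ---------------------------------------------------------------------------
# Skip-gram with negative sampling


def skipgram_pairs(
    tokens: Sequence[int], window_size: int
) -> Iterator[tuple[int, int]]:
    """(center, context) pairs within ±window_size, truncated at the ends."""
    if window_size < 1:
        raise InvalidConfigError("window_size must be >= 1")
    n = len(tokens)
    for i in range(n):
        lo = max(0, i - window_size)
        hi = min(n, i + window_size + 1)
        for j in range(lo, hi):
            if j != i:
                yield int(tokens[i]), int(tokens[j])


def unigram_noise(counts: np.ndarray, power: float = 0.75) -> np.ndarray:
    """Smoothed unigram noise distribution for negative sampling."""
    p = np.asarray(counts, dtype=float) ** power
    return p / p.sum()


def sgns_loss_and_grads(
    weights: SkipGramWeights,
    center: int,
    context: int,
    negatives: Sequence[int],
) -> tuple[float, dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Negative-sampling objective and its gradients for one pair.

    loss = -log σ(u_ctx·v) - Σ_neg log σ(-u_neg·v).  Returns the loss and
    sparse gradients keyed by row: one entry for the input-embedding row
    of ``center``, entries in the second dict for the output-embedding
    rows of ``context`` and each negative.
    """
    v = weights.w_in[center]
    grad_in: dict[int, np.ndarray] = {center: np.zeros_like(v)}
    grad_out: dict[int, np.ndarray] = {}
    s = _sigmoid(np.array([weights.w_out[context] @ v]))[0]
    loss = -np.log(s)
    coeff = s - 1.0
    grad_in[center] += coeff * weights.w_out[context]
    grad_out[context] = grad_out.get(context, 0.0) + coeff * v
    for neg in negatives:
        sn = _sigmoid(np.array([weights.w_out[neg] @ v]))[0]
        loss += -np.log(1.0 - sn)
        grad_in[center] += sn * weights.w_out[neg]
        grad_out[neg] = grad_out.get(neg, 0.0) + sn * v
    return float(loss), grad_in, grad_out


def sample_negatives(
    rng: np.random.Generator,
    noise: np.ndarray,
    contexts: np.ndarray,
    k: int,
) -> np.ndarray:
    """Draw k noise words per pair from a distribution excluding the true
    context word (collisions are redrawn)."""
    b = contexts.shape[0]
    negs = rng.choice(noise.shape[0], size=(b, k), p=noise)
    bad = negs == contexts[:, None]
    while bad.any():
        negs[bad] = rng.choice(noise.shape[0], size=int(bad.sum()), p=noise)
        bad = negs == contexts[:, None]
    return negs


def skipgram_update(
    weights: SkipGramWeights,
    pair: tuple[int, int],
    k_negatives: int,
    noise_distribution: np.ndarray,
    learning_rate: float,
    rng: np.random.Generator,
) -> float:
    """One stochastic-gradient step on the negative-sampling objective."""
    center, context = pair
    negatives = sample_negatives(
        rng, noise_distribution, np.asarray([context]), k_negatives
    )[0]
    loss, grad_in, grad_out = sgns_loss_and_grads(
        weights, center, context, negatives
    )
    for row, g in grad_in.items():
        weights.w_in[row] -= learning_rate * g
    for row, g in grad_out.items():
        weights.w_out[row] -= learning_rate * g
    return loss


def sgns_batch_update(
    weights: SkipGramWeights,
    centers: np.ndarray,
    contexts: np.ndarray,
    negatives: np.ndarray,
    learning_rate: float,
) -> float:
    """Vectorized SGD over a batch of (center, context, negatives) triples.

    Equivalent to applying `sgns_loss_and_grads` pair by pair except that
    all pairs in the batch read the same pre-update weights.
    """
    v = weights.w_in[centers]  # (B, H)
    u_pos = weights.w_out[contexts]  # (B, H)
    u_neg = weights.w_out[negatives]  # (B, k, H)
    s_pos = _sigmoid(np.einsum("bh,bh->b", u_pos, v))
    s_neg = _sigmoid(np.einsum("bkh,bh->bk", u_neg, v))
    loss = float((-np.log(s_pos) - np.log(1.0 - s_neg).sum(axis=1)).mean())
    coeff_pos = (s_pos - 1.0)[:, None]  # (B, 1)
    dv = coeff_pos * u_pos + np.einsum("bk,bkh->bh", s_neg, u_neg)
    d_upos = coeff_pos * v
    d_uneg = s_neg[:, :, None] * v[:, None, :]
    np.add.at(weights.w_in, centers, -learning_rate * dv)
    np.add.at(weights.w_out, contexts, -learning_rate * d_upos)
    np.add.at(
        weights.w_out,
        negatives.reshape(-1),
        -learning_rate * d_uneg.reshape(-1, weights.hidden_size),
    )
    return loss
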