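"""Dual-branch recurrent synthesis of neural-code event sequences.

A recording is abstracted as an ordered sequence of (code type, inter-peak
interval) events. A two-layer recurrent network (LSTM by default, GRU
selectable) with 128 hidden units per layer receives, at each step, a
learnable embedding of the code type plus the interval as a continuous
feature, and predicts the next event through two heads: a softmax over
code types (categorical cross-entropy) and a non-negative interval
regressor (ReLU with an additive floor of one sample period; mean squared
error). Training uses Adam with early stopping on a held-out split.

Generation starts from a seed drawn from the corpus and runs the model
autoregressively. A statistical control mechanism keeps the generated
code-type frequencies near a target distribution by multiplicatively
reweighting the predicted probabilities with ``(target / running)^beta``
before sampling; generation stops once every *common* code type (top-k by
training frequency) has reached a minimum occurrence quota, or at a hard
length cap (flagged). Fidelity is assessed by a chi-square test on the
code-frequency tables and a two-sample Kolmogorov–Smirnov test on the
interval distributions.

The whole engine is plain NumPy with analytic backpropagation; gradients
are verified against finite differences in the test suite, and every
random draw flows through a seeded generator, so training and generation
are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from neurocode.errors import ConfigError, ValidationError
from neurocode.io_formats import Recording, RecordingMeta


# ---------------------------------------------------------------------------
# Event sequences and their tensor encoding
# ---------------------------------------------------------------------------


@dataclass
class EventSequence:
    """Ordered (code type, interval-to-next-peak) pairs."""

    code_ids: list[str]
    intervals_ms: np.ndarray
    source: str = "recorded"  # "recorded" | "generated"

    def __post_init__(self):
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        if len(self.code_ids) != self.intervals_ms.size:
            raise ValidationError("code_ids and intervals_ms length mismatch")
        if self.intervals_ms.size and self.intervals_ms.min() <= 0:
            raise ValidationError("intervals must be > 0")
        if self.source not in ("recorded", "generated"):
            raise ValidationError(f"unknown source label {self.source!r}")

    def __len__(self) -> int:
        return len(self.code_ids)


def encode_events(
    sequences: list[EventSequence], code_list: list[str]
) -> dict:
    """Encode sequences as index/one-hot arrays plus interval vectors.

    ``decode_events`` inverts this encoding exactly. Raises on codes absent
    from ``code_list``.
    """
    index = {c: i for i, c in enumerate(code_list)}
    seq_idx, seq_onehot, seq_iv = [], [], []
    for s in sequences:
        try:
            idx = np.array([index[c] for c in s.code_ids], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"unknown code {exc.args[0]!r}") from None
        onehot = np.zeros((len(s), len(code_list)))
        onehot[np.arange(len(s)), idx] = 1.0
        seq_idx.append(idx)
        seq_onehot.append(onehot)
        seq_iv.append(s.intervals_ms.copy())
    return {
        "code_list": list(code_list),
        "indices": seq_idx,
        "onehot": seq_onehot,
        "intervals_ms": seq_iv,
    }


def decode_events(encoded: dict, source: str = "recorded") -> list[EventSequence]:
    codes = encoded["code_list"]
    return [
        EventSequence(
            code_ids=[codes[i] for i in idx],
            intervals_ms=iv,
            source=source,
        )
        for idx, iv in zip(encoded["indices"], encoded["intervals_ms"])
    ]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SeqModelConfig:
    hidden_units: int = 128
    n_layers: int = 2
    dropout: float = 0.3
    learning_rate: float = 1e-3
    max_epochs: int = 50
    patience: int = 5
    loss_weight_type: float = 1.0
    loss_weight_interval: float = 1.0
    seed: int = 0
    embedding_dim: int = 16
    window: int = 32
    batch_size: int = 32
    cell_type: str = "lstm"  # "lstm" | "gru"
    val_fraction: float = 0.1
    grad_clip: float = 5.0
    min_interval_ms: float = 1.0 / 30.0  # one sample period at 30 kHz

    def __post_init__(self):
        if min(self.hidden_units, self.n_layers, self.embedding_dim) < 1:
            raise ConfigError("architecture sizes must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout must be in [0, 1)")
        if self.learning_rate <= 0 or self.max_epochs < 1:
            raise ConfigError("learning_rate and max_epochs must be positive")
        if self.cell_type not in ("lstm", "gru"):
            raise ConfigError(f"unknown cell type {self.cell_type!r}")
        if self.loss_weight_type <= 0 or self.loss_weight_interval <= 0:
            raise ConfigError("loss weights must be positive")


@dataclass
class GenControl:
    """Generation stopping rule and statistical control parameters."""

    target_distribution: dict[str, float] | None = None
    min_common_occurrences: int = 70
    common_top_k: int = 70
    max_length: int = 50000
    temperature: float = 1.0
    beta: float = 1.0  # strength of the frequency reweighting
    interval_noise: bool = True

    def __post_init__(self):
        if self.min_common_occurrences < 1:
            raise ConfigError("min_common_occurrences must be >= 1")
        if self.target_distribution is not None:
            total = sum(self.target_distribution.values())
            if abs(total - 1.0) > 1e-8:
                raise ConfigError("target distribution must sum to 1")
        if self.temperature < 0:
            raise ConfigError("temperature must be >= 0")


# ---------------------------------------------------------------------------
# Recurrent cells (NumPy, analytic gradients)
# ---------------------------------------------------------------------------


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -40, 40)))


class _LSTMLayer:
    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(n_in + n_hidden)
        self.Wx = rng.uniform(-s, s, size=(n_in, 4 * n_hidden))
        self.Wh = rng.uniform(-s, s, size=(n_hidden, 4 * n_hidden))
        self.b = np.zeros(4 * n_hidden)
        self.b[n_hidden : 2 * n_hidden] = 1.0  # forget-gate bias
        self.H = n_hidden

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def init_state(self, batch: int):
        return (np.zeros((batch, self.H)), np.zeros((batch, self.H)))

    def step(self, x, state):
        h_prev, c_prev = state
        H = self.H
        z = x @ self.Wx + h_prev @ self.Wh + self.b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c = f * c_prev + i * g
        h = o * np.tanh(c)
        cache = (x, h_prev, c_prev, i, f, g, o, c)
        return h, (h, c), cache

    def backward_step(self, dh, dc_next, cache, grads):
        x, h_prev, c_prev, i, f, g, o, c = cache
        tc = np.tanh(c)
        dc = dc_next + dh * o * (1.0 - tc * tc)
        do = dh * tc
        di, df, dg = dc * g, dc * c_prev, dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        gWx, gWh, gb = grads
        gWx += x.T @ dz
        gWh += h_prev.T @ dz
        gb += dz.sum(axis=0)
        dx = dz @ self.Wx.T
        dh_prev = dz @ self.Wh.T
        dc_prev = dc * f
        return dx, dh_prev, dc_prev


class _GRULayer:
    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(n_in + n_hidden)
        self.Wx = rng.uniform(-s, s, size=(n_in, 3 * n_hidden))  # z, r, n
        self.Wh = rng.uniform(-s, s, size=(n_hidden, 3 * n_hidden))
        self.b = np.zeros(3 * n_hidden)
        self.H = n_hidden

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def init_state(self, batch: int):
        return np.zeros((batch, self.H))

    def step(self, x, state):
        h_prev = state
        H = self.H
        ax = x @ self.Wx + self.b
        ah = h_prev @ self.Wh
        z = _sigmoid(ax[:, :H] + ah[:, :H])
        r = _sigmoid(ax[:, H : 2 * H] + ah[:, H : 2 * H])
        hn = ah[:, 2 * H :]
        n = np.tanh(ax[:, 2 * H :] + r * hn)
        h = (1.0 - z) * n + z * h_prev
        cache = (x, h_prev, z, r, n, hn)
        return h, h, cache

    def backward_step(self, dh, _unused, cache, grads):
        x, h_prev, z, r, n, hn = cache
        H = self.H
        dn = dh * (1.0 - z)
        dz = dh * (h_prev - n)
        dh_prev = dh * z
        dan = dn * (1.0 - n * n)
        dr = dan * hn
        dhn = dan * r
        daz = dz * z * (1.0 - z)
        dar = dr * r * (1.0 - r)
        dax = np.concatenate([daz, dar, dan], axis=1)
        dah = np.concatenate([daz, dar, dhn], axis=1)
        gWx, gWh, gb = grads
        gWx += x.T @ dax
        gWh += h_prev.T @ dah
        gb += dax.sum(axis=0)
        dx = dax @ self.Wx.T
        dh_prev = dh_prev + dah @ self.Wh.T
        return dx, dh_prev, None


# ---------------------------------------------------------------------------
# The dual-branch sequence model
# ---------------------------------------------------------------------------


class SequenceModel:
    """Two-layer recurrent network with type (softmax) and interval (ReLU)
    heads over embedded (code, interval) events."""

    def __init__(self, code_list: list[str], config: SeqModelConfig):
        self.code_list = list(code_list)
        self.config = config
        self.V = len(code_list)
        if self.V < 1:
            raise ConfigError("empty code alphabet")
        rng = np.random.default_rng(config.seed)
        H, E = config.hidden_units, config.embedding_dim
        self.embedding = rng.normal(0, 0.1, size=(self.V, E))
        cell = _LSTMLayer if config.cell_type == "lstm" else _GRULayer
        self.layers = []
        n_in = E + 1
        for _ in range(config.n_layers):
            self.layers.append(cell(n_in, H, rng))
            n_in = H
        s = 1.0 / np.sqrt(H)
        self.W_type = rng.uniform(-s, s, size=(H, self.V))
        self.b_type = np.zeros(self.V)
        self.W_iv = rng.uniform(-s, s, size=(H, 1))
        # bias starts at the normalised mean interval (1.0) so the ReLU
        # head does not initialise dead
        self.b_iv = np.ones(1)
        # interval normalisation (set from the training corpus)
        self.iv_mean = 1.0
        self.iv_resid_sd = 0.0
        self._adam_m = None
        self._adam_v = None
        self._adam_t = 0

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        ps = [self.embedding]
        for layer in self.layers:
            ps.extend(layer.params())
        ps.extend([self.W_type, self.b_type, self.W_iv, self.b_iv])
        return ps

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w

    # -- forward / backward over a window batch -----------------------------

    def _forward(self, idx, iv, dropout_rng=None):
        """idx, iv: (B, T) int / float arrays. Returns loss pieces + caches.

        Predicts event t+1 from events <= t, so effective steps are T-1.
        """
        B, T = idx.shape
        cfg = self.config
        states = [layer.init_state(B) for layer in self.layers]
        caches, masks, hs = [], [], []
        iv_n = iv / self.iv_mean
        for t in range(T - 1):
            x = np.concatenate(
                [self.embedding[idx[:, t]], iv_n[:, t : t + 1]], axis=1
            )
            step_caches, step_masks = [], []
            for li, layer in enumerate(self.layers):
                h, states[li], cache = layer.step(x, states[li])
                step_caches.append(cache)
                if dropout_rng is not None and cfg.dropout > 0 and li < len(self.layers) - 1:
                    mask = (
                        dropout_rng.random(h.shape) >= cfg.dropout
                    ) / (1.0 - cfg.dropout)
                    h = h * mask
                    step_masks.append(mask)
                else:
                    step_masks.append(None)
                x = h
            caches.append(step_caches)
            masks.append(step_masks)
            hs.append(x)
        return np.asarray(hs), caches, masks  # hs: (T-1, B, H)

    def _heads(self, hs):
        logits = hs @ self.W_type + self.b_type  # (T-1, B, V)
        iv_lin = (hs @ self.W_iv + self.b_iv)[..., 0]  # (T-1, B)
        iv_pred = np.maximum(iv_lin, 0.0)  # ReLU non-negativity
        return logits, iv_lin, iv_pred

    def _loss_and_grads(self, idx, iv, dropout_rng=None):
        cfg = self.config
        B, T = idx.shape
        hs, caches, masks = self._forward(idx, iv, dropout_rng)
        logits, iv_lin, iv_pred = self._heads(hs)
        tgt_idx = idx[:, 1:].T  # (T-1, B)
        tgt_iv = (iv[:, 1:] / self.iv_mean).T

        # softmax CE
        z = logits - logits.max(axis=2, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=2, keepdims=True)
        steps = (T - 1) * B
        tt, bb = np.meshgrid(
            np.arange(T - 1), np.arange(B), indexing="ij"
        )
        ce = -np.log(np.maximum(probs[tt, bb, tgt_idx], 1e-12)).mean()
        mse = ((iv_pred - tgt_iv) ** 2).mean()
        loss = cfg.loss_weight_type * ce + cfg.loss_weight_interval * mse

        # head gradients
        dlogits = probs.copy()
        dlogits[tt, bb, tgt_idx] -= 1.0
        dlogits *= cfg.loss_weight_type / steps
        div = (
            2.0
            * cfg.loss_weight_interval
            / steps
            * (iv_pred - tgt_iv)
            * (iv_lin > 0)
        )

        grads = [np.zeros_like(p) for p in self.parameters()]
        gi = {id(p): g for p, g in zip(self.parameters(), grads)}
        g_emb = gi[id(self.embedding)]
        g_Wt, g_bt = gi[id(self.W_type)], gi[id(self.b_type)]
        g_Wi, g_bi = gi[id(self.W_iv)], gi[id(self.b_iv)]
        layer_grads = [
            tuple(gi[id(p)] for p in layer.params()) for layer in self.layers
        ]

        n_layers = len(self.layers)
        dh_next = [np.zeros((B, self.config.hidden_units)) for _ in range(n_layers)]
        dc_next = [np.zeros((B, self.config.hidden_units)) for _ in range(n_layers)]
        for t in range(T - 2, -1, -1):
            h_t = hs[t]
            g_Wt += h_t.T @ dlogits[t]
            g_bt += dlogits[t].sum(axis=0)
            g_Wi += h_t.T @ div[t][:, None]
            g_bi += div[t].sum(keepdims=True)
            dh = dlogits[t] @ self.W_type.T + div[t][:, None] @ self.W_iv.T
            for li in range(n_layers - 1, -1, -1):
                # the dropout mask sits on the inter-layer path only; the
                # recurrent gradient from t+1 bypasses it
                if masks[t][li] is not None:
                    dh = dh * masks[t][li]
                d = dh + dh_next[li]
                dx, dh_prev, dc_prev = self.layers[li].backward_step(
                    d, dc_next[li], caches[t][li], layer_grads[li]
                )
                dh_next[li] = dh_prev
                if dc_prev is not None:
                    dc_next[li] = dc_prev
                dh = dx
            # dh is now the gradient w.r.t. the input vector at step t
            np.add.at(g_emb, idx[:, t], dh[:, : self.config.embedding_dim])
            # (interval input gradient not needed for any parameter)

        # global-norm gradient clipping
        norm = np.sqrt(sum(float((g * g).sum()) for g in grads))
        if cfg.grad_clip > 0 and norm > cfg.grad_clip:
            for g in grads:
                g *= cfg.grad_clip / norm
        return loss, float(ce), float(mse), grads

    def evaluate(self, idx, iv) -> tuple[float, float, float]:
        """Loss on a window batch without dropout or gradients."""
        cfg = self.config
        hs, _, _ = self._forward(idx, iv, dropout_rng=None)
        logits, _, iv_pred = self._heads(hs)
        B, T = idx.shape
        tgt_idx = idx[:, 1:].T
        tgt_iv = (iv[:, 1:] / self.iv_mean).T
        z = logits - logits.max(axis=2, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=2, keepdims=True)
        tt, bb = np.meshgrid(np.arange(T - 1), np.arange(B), indexing="ij")
        ce = -np.log(np.maximum(probs[tt, bb, tgt_idx], 1e-12)).mean()
        mse = ((iv_pred - tgt_iv) ** 2).mean()
        return (
            cfg.loss_weight_type * ce + cfg.loss_weight_interval * mse,
            float(ce),
            float(mse),
        )

    def _adam_update(self, grads):
        cfg = self.config
        if self._adam_m is None:
            self._adam_m = [np.zeros_like(p) for p in self.parameters()]
            self._adam_v = [np.zeros_like(p) for p in self.parameters()]
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for p, g, m, v in zip(
            self.parameters(), grads, self._adam_m, self._adam_v
        ):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mh = m / (1 - b1**t)
            vh = v / (1 - b2**t)
            p -= cfg.learning_rate * mh / (np.sqrt(vh) + eps)

    # -- single-step interface for generation -------------------------------

    def init_state(self, batch: int = 1):
        return [layer.init_state(batch) for layer in self.layers]

    def step(self, code_idx: int, interval_ms: float, states):
        x = np.concatenate(
            [
                self.embedding[[code_idx]],
                np.array([[interval_ms / self.iv_mean]]),
            ],
            axis=1,
        )
        for li, layer in enumerate(self.layers):
            h, states[li], _ = layer.step(x, states[li])
            x = h
        logits = (x @ self.W_type + self.b_type)[0]
        iv_pred = max(float((x @ self.W_iv + self.b_iv)[0, 0]), 0.0)
        return logits, iv_pred * self.iv_mean, states


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _windows(sequences_idx, sequences_iv, window: int):
    idx_w, iv_w = [], []
    for idx, iv in zip(sequences_idx, sequences_iv):
        n = idx.size
        if n < 2:
            continue
        for s in range(0, max(n - 1, 1), window - 1):
            chunk = slice(s, min(s + window, n))
            if chunk.stop - chunk.start < 2:
                continue
            ci = idx[chunk]
            cv = iv[chunk]
            if ci.size < window:  # left-pad by repeating the first event
                pad = window - ci.size
                ci = np.concatenate([np.full(pad, ci[0]), ci])
                cv = np.concatenate([np.full(pad, cv[0]), cv])
            idx_w.append(ci)
            iv_w.append(cv)
    if not idx_w:
        raise ValidationError("corpus has no sequence with >= 2 events")
    return np.asarray(idx_w), np.asarray(iv_w)


def train_model(
    sequences: list[EventSequence],
    config: SeqModelConfig | None = None,
    code_list: list[str] | None = None,
) -> tuple[SequenceModel, dict]:
    """Train the dual-branch model; returns (model, training log).

    The log records per-epoch type loss (cross-entropy) and interval loss
    (MSE) separately, for training and validation splits; the weights kept
    are those of the best validation epoch (early stopping).
    """
    if not sequences:
        raise ValidationError("empty corpus")
    config = config or SeqModelConfig()
    if code_list is None:
        code_list = sorted({c for s in sequences for c in s.code_ids})
    enc = encode_events(sequences, code_list)
    all_iv = np.concatenate(enc["intervals_ms"])
    flags = []
    if len(code_list) == 1 and np.allclose(all_iv, all_iv[0]):
        flags.append("degenerate corpus: single code type and constant interval")
        warnings.warn(flags[-1])

    model = SequenceModel(code_list, config)
    model.iv_mean = float(max(all_iv.mean(), 1e-9))
    counts = np.bincount(
        np.concatenate(enc["indices"]), minlength=len(code_list)
    ).astype(float)
    model.train_frequencies = counts / counts.sum()

    idx_w, iv_w = _windows(enc["indices"], enc["intervals_ms"], config.window)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(idx_w.shape[0])
    n_val = max(int(round(config.val_fraction * order.size)), 1) if order.size > 1 else 0
    val_sel, train_sel = order[:n_val], order[n_val:]
    if train_sel.size == 0:
        train_sel, val_sel = order, order
    dropout_rng = np.random.default_rng(config.seed + 1)

    log = {"epoch": [], "train_type_loss": [], "train_interval_loss": [],
           "val_type_loss": [], "val_interval_loss": [], "val_loss": [],
           "flags": flags}
    best_val, best_weights, best_epoch, bad = np.inf, None, 0, 0
    for epoch in range(config.max_epochs):
        perm = rng.permutation(train_sel)
        ce_acc, mse_acc, nb = 0.0, 0.0, 0
        for s in range(0, perm.size, config.batch_size):
            batch = perm[s : s + config.batch_size]
            _, ce, mse, grads = model._loss_and_grads(
                idx_w[batch], iv_w[batch], dropout_rng
            )
            model._adam_update(grads)
            ce_acc += ce
            mse_acc += mse
            nb += 1
        if val_sel.size:
            val_loss, val_ce, val_mse = model.evaluate(idx_w[val_sel], iv_w[val_sel])
        else:
            val_loss, val_ce, val_mse = model.evaluate(idx_w[train_sel], iv_w[train_sel])
        log["epoch"].append(epoch)
        log["train_type_loss"].append(ce_acc / max(nb, 1))
        log["train_interval_loss"].append(mse_acc / max(nb, 1))
        log["val_type_loss"].append(val_ce)
        log["val_interval_loss"].append(val_mse)
        log["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val, best_weights, best_epoch, bad = (
                val_loss,
                model.get_weights(),
                epoch,
                0,
            )
        else:
            bad += 1
            if bad >= config.patience:
                break
    if best_weights is not None:
        model.set_weights(best_weights)
    log["best_epoch"] = best_epoch
    log["best_val_loss"] = float(best_val)
    # residual SD of the interval head on the training windows (used as the
    # timing-control noise scale during generation)
    hs, _, _ = model._forward(idx_w[train_sel], iv_w[train_sel])
    _, _, iv_pred = model._heads(hs)
    resid = (iv_w[train_sel][:, 1:].T - iv_pred * model.iv_mean).ravel()
    model.iv_resid_sd = float(resid.std())
    # empirical residual pool: the timing arm of the statistical control
    # draws from it so generated intervals match the training marginal
    if resid.size > 5000:
        resid = np.random.default_rng(config.seed).choice(resid, 5000, replace=False)
    model.iv_residuals = np.sort(resid)
    return model, log


# ---------------------------------------------------------------------------
# Generation with statistical control
# ---------------------------------------------------------------------------


def generate_sequence(
    model: SequenceModel,
    seed_events: EventSequence,
    control: GenControl | None = None,
    seed: int = 0,
) -> tuple[EventSequence, dict]:
    """Autoregressive generation under the statistical control mechanism.

    Stops once every common code type (top-k of the training distribution)
    has at least ``min_common_occurrences`` occurrences, or at
    ``max_length`` (reported as ``capped``). Intervals are strictly
    positive: the ReLU head output is floored at one sample period, with
    optional Gaussian timing noise at the training residual scale.
    """
    control = control or GenControl()
    rng = np.random.default_rng(seed)
    index = {c: i for i, c in enumerate(model.code_list)}
    if not len(seed_events):
        raise ValidationError("seed_events must be non-empty")
    for c in seed_events.code_ids:
        if c not in index:
            raise ValidationError(f"seed code {c!r} not in model alphabet")

    train_freq = getattr(
        model, "train_frequencies", np.full(model.V, 1.0 / model.V)
    )
    target = np.asarray(
        [
            control.target_distribution.get(c, 0.0)
            if control.target_distribution
            else train_freq[i]
            for i, c in enumerate(model.code_list)
        ]
    )
    k = min(control.common_top_k, model.V)
    common = set(np.argsort(-train_freq, kind="stable")[:k])

    states = model.init_state(1)
    logits, iv_pred = None, None
    for c, iv in zip(seed_events.code_ids, seed_events.intervals_ms):
        logits, iv_pred, states = model.step(index[c], iv, states)

    counts = np.zeros(model.V)
    gen_codes: list[str] = []
    gen_iv: list[float] = []
    floor = model.config.min_interval_ms
    capped = False
    while True:
        if control.temperature == 0:
            p = np.zeros(model.V)
            p[np.argmax(logits)] = 1.0
        else:
            z = logits / control.temperature
            z = z - z.max()
            p = np.exp(z)
            p /= p.sum()
        if control.beta > 0 and counts.sum() > 0:
            running = counts / counts.sum()
            w = (target / np.maximum(running, 1e-4)) ** control.beta
            p = p * w
            total = p.sum()
            p = p / total if total > 0 else np.full(model.V, 1.0 / model.V)
        if control.temperature == 0:
            c_next = int(np.argmax(p))
        else:
            c_next = int(rng.choice(model.V, p=p))
        iv_next = iv_pred
        if control.interval_noise:
            pool = getattr(model, "iv_residuals", None)
            if pool is not None and pool.size:
                iv_next += float(rng.choice(pool))
            elif model.iv_resid_sd > 0:
                iv_next += model.iv_resid_sd * rng.normal()
        iv_next = max(iv_next, floor)
        gen_codes.append(model.code_list[c_next])
        gen_iv.append(iv_next)
        counts[c_next] += 1
        if common and all(counts[i] >= control.min_common_occurrences for i in common):
            break
        if len(gen_codes) >= control.max_length:
            capped = True
            warnings.warn("length cap reached before the occurrence quota")
            break
        logits, iv_pred, states = model.step(c_next, iv_next, states)

    seq = EventSequence(
        code_ids=gen_codes, intervals_ms=np.asarray(gen_iv), source="generated"
    )
    info = {
        "capped": capped,
        "counts": {model.code_list[i]: int(counts[i]) for i in range(model.V)},
        "common_codes": [model.code_list[i] for i in sorted(common)],
        "quota_met": not capped,
    }
    return seq, info


# ---------------------------------------------------------------------------
# Fidelity validation
# ---------------------------------------------------------------------------


def validate_generated(
    generated: EventSequence | list[EventSequence],
    training: EventSequence | list[EventSequence],
    alpha: float = 0.01,
) -> dict:
    """Chi-square on code frequencies + two-sample K-S on intervals.

    The code universe is the union of both alphabets (absent codes count 0,
    with a warning on mismatch). Reports statistics, p-values, the
    per-code frequency table, and a pass flag at the declared alpha
    (pass = no significant difference on either test).
    """
    gen = [generated] if isinstance(generated, EventSequence) else list(generated)
    trn = [training] if isinstance(training, EventSequence) else list(training)
    if not gen or not trn or not any(len(s) for s in gen) or not any(len(s) for s in trn):
        raise ValidationError("both generated and training must be non-empty")
    g_codes = [c for s in gen for c in s.code_ids]
    t_codes = [c for s in trn for c in s.code_ids]
    g_iv = np.concatenate([s.intervals_ms for s in gen])
    t_iv = np.concatenate([s.intervals_ms for s in trn])

    universe = sorted(set(g_codes) | set(t_codes))
    if set(g_codes) != set(t_codes):
        warnings.warn("alphabet mismatch; using the union with zero counts")
    gc = np.array([g_codes.count(c) for c in universe], dtype=float)
    tc = np.array([t_codes.count(c) for c in universe], dtype=float)
    g_freq = gc / gc.sum()
    t_freq = tc / tc.sum()
    if np.array_equal(gc, tc):
        chi2, chi2_p = 0.0, 1.0
    else:
        table = np.vstack([gc, tc])
        table = table[:, table.sum(axis=0) > 0]
        chi2, chi2_p, _, _ = stats.chi2_contingency(table)
    if g_iv.size == t_iv.size and np.allclose(np.sort(g_iv), np.sort(t_iv)):
        ks, ks_p = 0.0, 1.0
    else:
        ks, ks_p = stats.ks_2samp(g_iv, t_iv)
    return {
        "codes": universe,
        "generated_freq": dict(zip(universe, g_freq)),
        "training_freq": dict(zip(universe, t_freq)),
        "chi2": float(chi2),
        "chi2_p": float(chi2_p),
        "ks": float(ks),
        "ks_p": float(ks_p),
        "alpha": alpha,
        "passed": bool(chi2_p > alpha and ks_p > alpha),
    }


# ---------------------------------------------------------------------------
# Stimulus rendering
# ---------------------------------------------------------------------------


def render_stimulus(
    events: EventSequence,
    library,
    rate_hz: float = 30000.0,
    uv_per_count: float = 0.0305,
) -> Recording:
    """Concatenate code templates at the event intervals on a zero baseline.

    Peaks are placed on the sample grid; consecutive peaks are separated by
    the (rounded) inter-peak intervals. The final event's interval is
    rendered as trailing silence. Intervals shorter than the template span
    overlap-add with a warning.
    """
    meta = RecordingMeta(
        sampling_rate_hz=rate_hz, n_channels=1, uv_per_count=uv_per_count
    )
    if len(events) == 0:
        return Recording(meta=meta, samples=np.zeros((1, 0), dtype=np.int16))
    templates = {t.code_id: t for t in library.codes}
    for c in events.code_ids:
        if c not in templates:
            raise ValidationError(f"code {c!r} not in library")
    gaps = np.maximum(np.rint(events.intervals_ms * 1e-3 * rate_hz), 1).astype(int)
    peaks = np.concatenate([[0], np.cumsum(gaps[:-1])])
    max_pre = max(t.alignment_index for t in templates.values())
    max_post = max(
        t.template_uv.size - t.alignment_index for t in templates.values()
    )
    offset = max_pre
    n = int(peaks[-1] + offset + max_post + gaps[-1])
    trace = np.zeros(n)
    overlap = False
    for c, pk, gap in zip(events.code_ids, peaks, gaps):
        t = templates[c]
        lo = offset + pk - t.alignment_index
        trace[lo : lo + t.template_uv.size] += t.template_uv
        if gap < t.template_uv.size - t.alignment_index:
            overlap = True
    if overlap:
        warnings.warn("some intervals are shorter than the template span; overlap-added")
    return Recording.from_uv(trace[None, :], meta)


def recover_sequence(
    rec: Recording,
    library,
    refractory_ms: float = 2.0,
) -> EventSequence:
    """Invert :func:`render_stimulus`: detect peaks and classify each one
    against the (fixed) library by best-match consistency.

    At zero noise this recovers the rendered (code, interval) sequence
    exactly (up to sample-grid quantisation of the intervals); the last
    event's trailing interval is unobservable and reported as one sample
    period.
    """
    from neurocode.codebook import sample_consistency
    from neurocode.detect import ThresholdEstimate, detect_peaks

    trace = rec.to_uv()[0]
    rate = rec.meta.sampling_rate_hz
    amp_min = min(np.max(np.abs(t.template_uv)) for t in library.codes)
    est = ThresholdEstimate(
        avg_uv=0.0,
        sd_uv=0.0,
        factor=0.0,
        threshold_uv=0.5 * amp_min,
        modified_threshold_uv=0.5 * amp_min,
    )
    events = detect_peaks(trace, est, rate, refractory_ms=refractory_ms)
    codes, times = [], []
    for t_s in events.time_s:
        pk = int(round(t_s * rate))
        best_id, best_score = None, -1.0
        for tmpl in library.codes:
            lo = pk - tmpl.alignment_index
            hi = lo + tmpl.template_uv.size
            if lo < 0 or hi > trace.size:
                continue
            score = sample_consistency(
                trace[lo:hi], tmpl.template_uv, library.tolerance
            )
            if score > best_score:
                best_id, best_score = tmpl.code_id, score
        if best_id is None or best_score < library.consistency_min:
            best_id = "?"
        codes.append(best_id)
        times.append(pk / rate)
    times = np.asarray(times)
    intervals = np.empty(times.size)
    if times.size:
        intervals[:-1] = np.diff(times) * 1e3
        intervals[-1] = 1e3 / rate
    return EventSequence(
        code_ids=codes, intervals_ms=intervals, source="generated"
    )
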