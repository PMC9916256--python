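"""Multilabel LSTM autoencoder (MLSTM-AE).

A single-layer LSTM encoder reads a length-T real-valued sequence; its
final hidden state feeds two heads:

* a decoder LSTM (same architecture) that reconstructs the *time-flipped*
  input, trained with a squared-error reconstruction loss
  ``L_rec = (1/N) sum_i sum_t ||x_it - xhat_it||^2`` (summed over time and
  feature, averaged over samples only);
* a fully connected multilabel classification head with per-label sigmoid
  scores, trained with ``L_cls = (1/N) sum_i sum_c (p_ic - phat_ic)^2``
  where ``phat_i = y_i / ||y_i||_1`` is the L1-normalized label row.

The joint objective is ``L = L_cls + gamma * L_rec``.

Everything — forward pass, backpropagation through time, Adam updates —
is implemented in numpy and verified against numerical gradients in the
test suite, so training is fully deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SequenceBatch",
    "ModelParams",
    "encode",
    "decode_reconstruct",
    "classify",
    "reconstruction_loss",
    "classification_loss",
    "total_loss",
    "train",
    "predict_scores",
]


@dataclass
class SequenceBatch:
    """N sequences of shape T x d with binary multilabel targets N x C."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y)
        if self.x.ndim != 3:
            raise ValueError(f"x must be N x T x d, got shape {self.x.shape}")
        if self.y.ndim != 2 or self.y.shape[0] != self.x.shape[0]:
            raise ValueError(f"y must be N x C with N={self.x.shape[0]}, got {self.y.shape}")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("label matrix entries must be 0 or 1")
        self.y = self.y.astype(float)

    @property
    def n(self) -> int:
        return self.x.shape[0]


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


@dataclass
class ModelParams:
    """All trainable weights of the MLSTM-AE.

    Gate order in the stacked recurrent matrices is (input, forget, cell,
    output); encoder and decoder share the same architecture shape. The
    decoder is an unconditioned generator: it receives zero input vectors
    and carries all signal through its recurrent state, which is
    initialized from the encoder's final hidden state.
    """

    enc_Wx: np.ndarray  # 4H x d
    enc_Wh: np.ndarray  # 4H x H
    enc_b: np.ndarray   # 4H
    dec_Wx: np.ndarray  # 4H x d
    dec_Wh: np.ndarray  # 4H x H
    dec_b: np.ndarray   # 4H
    dec_Wo: np.ndarray  # d x H, projects decoder state to a reconstruction step
    dec_bo: np.ndarray  # d
    cls_W: np.ndarray   # C x H
    cls_b: np.ndarray   # C
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.enc_Wx.shape != self.dec_Wx.shape or self.enc_Wh.shape != self.dec_Wh.shape:
            raise ValueError("encoder and decoder must have identical architecture shape")

    @property
    def hidden(self) -> int:
        return self.enc_Wh.shape[1]

    @property
    def d_in(self) -> int:
        return self.enc_Wx.shape[1]

    @property
    def n_labels(self) -> int:
        return self.cls_W.shape[0]

    def weight_fields(self) -> list[str]:
        return [
            "enc_Wx", "enc_Wh", "enc_b",
            "dec_Wx", "dec_Wh", "dec_b", "dec_Wo", "dec_bo",
            "cls_W", "cls_b",
        ]

    @classmethod
    def init(cls, d: int, hidden: int, n_labels: int, rng: np.random.Generator,
             gamma: float = 1.0) -> "ModelParams":
        """Glorot-uniform initialization with the forget-gate bias at +1."""
        def glorot(rows: int, cols: int) -> np.ndarray:
            s = np.sqrt(6.0 / (rows + cols))
            return rng.uniform(-s, s, size=(rows, cols))

        H = hidden
        enc_b = np.zeros(4 * H)
        dec_b = np.zeros(4 * H)
        enc_b[H:2 * H] = 1.0
        dec_b[H:2 * H] = 1.0
        return cls(
            enc_Wx=glorot(4 * H, d), enc_Wh=glorot(4 * H, H), enc_b=enc_b,
            dec_Wx=glorot(4 * H, d), dec_Wh=glorot(4 * H, H), dec_b=dec_b,
            dec_Wo=glorot(d, H), dec_bo=np.zeros(d),
            cls_W=glorot(n_labels, H), cls_b=np.zeros(n_labels),
            gamma=gamma,
        )

    def copy(self) -> "ModelParams":
        kw = {f: getattr(self, f).copy() for f in self.weight_fields()}
        return ModelParams(gamma=self.gamma, **kw)


def _lstm_step(x_t, h_prev, c_prev, Wx, Wh, b):
    H = h_prev.shape[1]
    a = x_t @ Wx.T + h_prev @ Wh.T + b
    i = _sigmoid(a[:, :H])
    f = _sigmoid(a[:, H:2 * H])
    g = np.tanh(a[:, 2 * H:3 * H])
    o = _sigmoid(a[:, 3 * H:])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c, (x_t, h_prev, c_prev, i, f, g, o, c)


def _lstm_forward(x, Wx, Wh, b, h0, c0):
    N, T, _ = x.shape
    H = Wh.shape[1]
    hs = np.empty((N, T, H))
    h, c = h0, c0
    caches = []
    for t in range(T):
        h, c, cache = _lstm_step(x[:, t, :], h, c, Wx, Wh, b)
        hs[:, t, :] = h
        caches.append(cache)
    return hs, c, caches


def _lstm_backward(dhs, dh_last, dc_last, caches, Wx, Wh):
    """BPTT for one LSTM. dhs: per-step external grads (may be None)."""
    N = caches[0][0].shape[0]
    H = Wh.shape[1]
    d = Wx.shape[1]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dx = np.zeros((N, len(caches), d))
    dh = dh_last.copy()
    dc = dc_last.copy()
    for t in range(len(caches) - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, o, c = caches[t]
        if dhs is not None:
            dh = dh + dhs[:, t, :]
        tc = np.tanh(c)
        da_o = dh * tc * o * (1 - o)
        dc = dc + dh * o * (1 - tc * tc)
        da_f = dc * c_prev * f * (1 - f)
        da_i = dc * g * i * (1 - i)
        da_g = dc * i * (1 - g * g)
        da = np.concatenate([da_i, da_f, da_g, da_o], axis=1)
        dWx += da.T @ x_t
        dWh += da.T @ h_prev
        db += da.sum(axis=0)
        dx[:, t, :] = da @ Wx
        dh = da @ Wh
        dc = dc * f
    return dWx, dWh, db, dx, dh, dc


def encode(batch: SequenceBatch, params: ModelParams):
    """Run the encoder; returns (hidden states N x T x H, final state N x H).

    The final state is exactly the T-th hidden state and is the sequence's
    vector representation.
    """
    x = batch.x if isinstance(batch, SequenceBatch) else np.asarray(batch, dtype=float)
    if x.shape[2] != params.d_in:
        raise ValueError(f"input feature width {x.shape[2]} != model d={params.d_in}")
    N = x.shape[0]
    H = params.hidden
    h0 = np.zeros((N, H))
    hs, _, _ = _lstm_forward(x, params.enc_Wx, params.enc_Wh, params.enc_b, h0, h0.copy())
    return hs, hs[:, -1, :]


def decode_reconstruct(final_state: np.ndarray, params: ModelParams, T: int) -> np.ndarray:
    """Decode T reconstruction steps from the encoder's final hidden state.

    The decoder's initial hidden state is ``final_state``; its output at
    step t is trained to match the time-flipped input, i.e. the target for
    ``x = (x_1, ..., x_T)`` is ``(x_T, ..., x_1)`` (see
    :func:`flip_time`).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    final_state = np.asarray(final_state, dtype=float)
    N, H = final_state.shape
    if H != params.hidden:
        raise ValueError(f"state width {H} != model hidden={params.hidden}")
    zeros_in = np.zeros((N, T, params.d_in))
    hs, _, _ = _lstm_forward(
        zeros_in, params.dec_Wx, params.dec_Wh, params.dec_b, final_state, np.zeros((N, H))
    )
    return hs @ params.dec_Wo.T + params.dec_bo


def flip_time(x: np.ndarray) -> np.ndarray:
    """Reconstruction target: the sequence reversed along the time axis."""
    return np.asarray(x)[:, ::-1, :]


def classify(final_state: np.ndarray, params: ModelParams) -> np.ndarray:
    """Per-label sigmoid scores from the encoder's final state; N x C in [0,1]."""
    final_state = np.asarray(final_state, dtype=float)
    if final_state.shape[1] != params.hidden:
        raise ValueError(
            f"state width {final_state.shape[1]} != model hidden={params.hidden}"
        )
    return _sigmoid(final_state @ params.cls_W.T + params.cls_b)


def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Squared reconstruction error, summed over time and feature, averaged over samples."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(np.sum((x - x_hat) ** 2) / x.shape[0])


def label_probabilities(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """L1-normalize label rows into ground-truth probability vectors.

    Returns (p_hat, valid_mask); rows with no active label are flagged
    invalid (their p_hat is left at zero) since normalization is undefined.
    """
    y = np.asarray(y, dtype=float)
    norms = y.sum(axis=1)
    valid = norms > 0
    p_hat = np.zeros_like(y)
    p_hat[valid] = y[valid] / norms[valid, None]
    return p_hat, valid


def classification_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error between predicted scores and L1-normalized labels.

    All-zero label rows are excluded (their normalized target is
    undefined) with a warning; the average runs over the retained rows.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    p_hat, valid = label_probabilities(y)
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} all-zero label row(s) excluded from classification loss",
            stacklevel=2,
        )
    if not valid.any():
        return 0.0
    diff = p[valid] - p_hat[valid]
    return float(np.sum(diff * diff) / valid.sum())


def total_loss(l_cls: float, l_rec: float, gamma: float) -> float:
    """Joint objective ``L = L_cls + gamma * L_rec``."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if not (np.isfinite(l_cls) and np.isfinite(l_rec)):
        raise ValueError("losses must be finite")
    return float(l_cls + gamma * l_rec)


def _forward_backward(params: ModelParams, x: np.ndarray, y: np.ndarray,
                      dropout: float, rng: np.random.Generator):
    """One joint forward/backward pass; returns (loss parts, gradients dict)."""
    N, T, d = x.shape
    H = params.hidden
    h0 = np.zeros((N, H))

    enc_hs, enc_c, enc_caches = _lstm_forward(
        x, params.enc_Wx, params.enc_Wh, params.enc_b, h0, h0.copy()
    )
    h_T = enc_hs[:, -1, :]

    if dropout > 0:
        mask = (rng.random(h_T.shape) >= dropout) / (1.0 - dropout)
        h_cls = h_T * mask
    else:
        mask = None
        h_cls = h_T

    # classification head
    p = _sigmoid(h_cls @ params.cls_W.T + params.cls_b)
    p_hat, valid = label_probabilities(y)
    n_valid = max(int(valid.sum()), 1)
    diff = (p - p_hat) * valid[:, None]
    l_cls = float(np.sum(diff * diff) / n_valid)

    # decoder
    zeros_in = np.zeros((N, T, d))
    dec_hs, dec_c, dec_caches = _lstm_forward(
        zeros_in, params.dec_Wx, params.dec_Wh, params.dec_b, h_T, np.zeros((N, H))
    )
    x_hat = dec_hs @ params.dec_Wo.T + params.dec_bo
    target = flip_time(x)
    l_rec = float(np.sum((x_hat - target) ** 2) / N)
    loss = l_cls + params.gamma * l_rec

    grads: dict[str, np.ndarray] = {}

    # classifier backward
    dp = 2.0 * diff / n_valid
    da_cls = dp * p * (1 - p)
    grads["cls_W"] = da_cls.T @ h_cls
    grads["cls_b"] = da_cls.sum(axis=0)
    dh_T_cls = da_cls @ params.cls_W
    if mask is not None:
        dh_T_cls = dh_T_cls * mask

    # decoder backward
    dx_hat = params.gamma * 2.0 * (x_hat - target) / N
    ddec_hs = dx_hat @ params.dec_Wo
    grads["dec_Wo"] = np.einsum("ntd,nth->dh", dx_hat, dec_hs)
    grads["dec_bo"] = dx_hat.sum(axis=(0, 1))
    dWx_d, dWh_d, db_d, _, dh0_dec, _ = _lstm_backward(
        ddec_hs, np.zeros((N, H)), np.zeros((N, H)), dec_caches,
        params.dec_Wx, params.dec_Wh,
    )
    grads["dec_Wx"], grads["dec_Wh"], grads["dec_b"] = dWx_d, dWh_d, db_d

    # encoder backward: final-state grad collects classifier + decoder paths
    dh_last = dh_T_cls + dh0_dec
    dWx_e, dWh_e, db_e, _, _, _ = _lstm_backward(
        None, dh_last, np.zeros((N, H)), enc_caches, params.enc_Wx, params.enc_Wh
    )
    grads["enc_Wx"], grads["enc_Wh"], grads["enc_b"] = dWx_e, dWh_e, db_e
    return loss, l_cls, l_rec, grads


DEFAULT_HYPER = {
    "hidden": 24,
    "learning_rate": 0.02,
    "batch_size": 32,
    "epochs": 60,
    "gamma": 1.0,
    "dropout": 0.0,
    "val_fraction": 0.2,
}


def train(data: SequenceBatch, hyper: dict | None = None, seed: int = 0):
    """Train the MLSTM-AE on ``data`` with Adam; fully seeded.

    One generator derived from ``seed`` governs the train/validation
    split, weight initialization, batch shuffling and dropout, so
    identical (data, hyper, seed) yields bit-identical loss histories.
    Returns ``(params, history)`` where ``params`` is the checkpoint with
    the lowest validation loss seen and ``history`` has one record per
    epoch with train/validation joint losses and their parts.
    """
    hp = dict(DEFAULT_HYPER)
    if hyper:
        hp.update(hyper)
    rng = np.random.default_rng(seed)
    N, T, d = data.x.shape
    C = data.y.shape[1]
    H = int(round(hp["hidden"]))
    batch_size = max(1, int(round(hp["batch_size"])))
    epochs = int(hp["epochs"])
    lr = float(hp["learning_rate"])
    dropout = float(hp["dropout"])
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")

    perm = rng.permutation(N)
    n_val = int(round(hp["val_fraction"] * N))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("empty training split")
    x_tr, y_tr = data.x[tr_idx], data.y[tr_idx]
    x_val, y_val = data.x[val_idx], data.y[val_idx]

    params = ModelParams.init(d, H, C, rng, gamma=float(hp["gamma"]))
    fields = params.weight_fields()
    m = {f: np.zeros_like(getattr(params, f)) for f in fields}
    v = {f: np.zeros_like(getattr(params, f)) for f in fields}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history: list[dict] = []
    best_val = np.inf
    best_params = params.copy()

    def eval_split(x, y):
        if len(x) == 0:
            return np.nan, np.nan, np.nan
        _, h_T = encode(SequenceBatch(x, y), params)
        p = classify(h_T, params)
        p_hat, valid = label_probabilities(y)
        nv = max(int(valid.sum()), 1)
        l_cls = float(np.sum(((p - p_hat) * valid[:, None]) ** 2) / nv)
        x_hat = decode_reconstruct(h_T, params, x.shape[1])
        l_rec = float(np.sum((x_hat - flip_time(x)) ** 2) / x.shape[0])
        return total_loss(l_cls, l_rec, params.gamma), l_cls, l_rec

    for epoch in range(epochs):
        order = rng.permutation(len(tr_idx))
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            loss, _, _, grads = _forward_backward(params, x_tr[idx], y_tr[idx], dropout, rng)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, step {step}: {loss}"
                )
            step += 1
            for f in fields:
                g = grads[f]
                m[f] = beta1 * m[f] + (1 - beta1) * g
                v[f] = beta2 * v[f] + (1 - beta2) * g * g
                mh = m[f] / (1 - beta1 ** step)
                vh = v[f] / (1 - beta2 ** step)
                getattr(params, f)[...] -= lr * mh / (np.sqrt(vh) + eps)

        tr_loss, tr_cls, tr_rec = eval_split(x_tr, y_tr)
        val_loss, val_cls, val_rec = eval_split(x_val, y_val)
        history.append({
            "epoch": epoch,
            "train_loss": tr_loss, "train_cls": tr_cls, "train_rec": tr_rec,
            "val_loss": val_loss, "val_cls": val_cls, "val_rec": val_rec,
        })
        monitor = val_loss if n_val > 0 else tr_loss
        if monitor < best_val:
            best_val = monitor
            best_params = params.copy()

    return best_params, history


def save_checkpoint(params: ModelParams, path, meta: dict | None = None) -> None:
    """Save weights as NPZ with a JSON sidecar (hyperparameters, seed, history)."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez(path, gamma=params.gamma,
             **{f: getattr(params, f) for f in params.weight_fields()})
    if meta is not None:
        with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)


def load_checkpoint(path) -> ModelParams:
    """Load weights saved by :func:`save_checkpoint`."""
    with np.load(path) as npz:
        kw = {f: npz[f] for f in npz.files if f != "gamma"}
        return ModelParams(gamma=float(npz["gamma"]), **kw)


def predict_scores(params: ModelParams, sequences: np.ndarray) -> np.ndarray:
    """Per-label sigmoid scores for raw sequences; rows preserve input order."""
    sequences = np.asarray(sequences, dtype=float)
    if sequences.ndim != 3 or sequences.shape[2] != params.d_in:
        raise ValueError(f"sequences must be N x T x {params.d_in}, got {sequences.shape}")
    dummy_y = np.zeros((sequences.shape[0], params.n_labels))
    _, h_T = encode(SequenceBatch(sequences, dummy_y), params)
    return classify(h_T, params)
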