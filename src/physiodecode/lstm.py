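"""NumPy bidirectional LSTM with exact backpropagation through time.

The reconstruction network is a single bidirectional LSTM layer over the ROI
channels, followed by dropout and two independent linear heads that emit one
RV and one HR value per frame.  Sequences of different lengths are padded to
the batch maximum and gated with a per-frame validity mask: at masked steps
the recurrent state passes through unchanged, and masked frames contribute
nothing to the loss or its gradients.

Everything here is plain NumPy; gradients are derived by hand and verified
against central finite differences in the test suite.

Parameter tensors (H = hidden size per direction, D = input channels), with
gate order (i, f, g, o) along the last axis:

==============  ==========  =============================================
name            shape       role
==============  ==========  =============================================
W_f, W_b        (D, 4H)     input-to-hidden, forward / backward direction
U_f, U_b        (H, 4H)     hidden-to-hidden
b_f, b_b        (4H,)       gate biases (forget-gate slice initialised to 1)
w_rv, w_hr      (2H, 1)     linear heads on the concatenated hidden state
b_rv, b_hr      (1,)        head biases
==============  ==========  =============================================
"""

from __future__ import annotations

import numpy as np

__all__ = ["BiLSTMParams", "init_params", "forward", "loss_and_grads", "AdamState"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


BiLSTMParams = dict  # name -> ndarray


def init_params(n_channels: int, hidden_size: int, rng: np.random.Generator) -> BiLSTMParams:
    """Uniform(-k, k) init with k = 1/sqrt(H); forget-gate bias starts at 1."""
    H, D = hidden_size, n_channels
    k = 1.0 / np.sqrt(H)

    def u(*shape):
        return rng.uniform(-k, k, size=shape)

    params = {}
    for tag in ("f", "b"):
        params[f"W_{tag}"] = u(D, 4 * H)
        params[f"U_{tag}"] = u(H, 4 * H)
        bias = u(4 * H)
        bias[H : 2 * H] = 1.0  # forget gate open at the start of training
        params[f"b_{tag}"] = bias
    for head in ("rv", "hr"):
        params[f"w_{head}"] = u(2 * H, 1)
        params[f"b_{head}"] = u(1)
    return params


def _lstm_direction(X, mask, W, U, b, reverse: bool):
    """Run one direction; returns hidden states (T,B,H) and the cache."""
    T, B, D = X.shape
    H = U.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.zeros((T, B, H))
    cache = []
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        m = mask[t][:, None]  # (B,1)
        z = X[t] @ W + h @ U + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        # masked steps carry state through unchanged
        h_next = m * h_new + (1.0 - m) * h
        c_next = m * c_new + (1.0 - m) * c
        cache.append((t, X[t], h, c, i, f, g, o, c_new, tanh_c, m))
        h, c = h_next, c_next
        hs[t] = h_next
    return hs, cache


def _lstm_direction_backward(dhs, cache, W, U):
    """Backprop one direction.  ``dhs`` is dL/d(hidden output) per step."""
    D = W.shape[0]
    T, B, H = dhs.shape
    dW = np.zeros_like(W)
    dU = np.zeros_like(U)
    db = np.zeros(4 * H)
    dX = np.zeros((T, B, D))
    dh_carry = np.zeros((B, H))
    dc_carry = np.zeros((B, H))
    for (t, x_t, h_prev, c_prev, i, f, g, o, c_new, tanh_c, m) in reversed(cache):
        dh_total = dhs[t] + dh_carry
        dh_valid = m * dh_total
        dh_passthru = (1.0 - m) * dh_total
        dc_valid = m * dc_carry
        dc_passthru = (1.0 - m) * dc_carry

        do = dh_valid * tanh_c
        dc_new = dc_valid + dh_valid * o * (1.0 - tanh_c**2)
        df = dc_new * c_prev
        di = dc_new * g
        dg = dc_new * i

        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dW += x_t.T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dX[t] = dz @ W.T
        dh_carry = dz @ U.T + dh_passthru
        dc_carry = dc_new * f + dc_passthru
    return dW, dU, db, dX


def forward(
    params: BiLSTMParams,
    X: np.ndarray,
    mask: np.ndarray | None = None,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Forward pass.

    Parameters
    ----------
    X : (T, B, D) padded input batch.
    mask : (T, B) validity mask; ``None`` means all frames valid.
    dropout : inverted-dropout rate on the concatenated hidden state; only
        active when ``rng`` is given (training mode).  Inference is
        deterministic.

    Returns ``(rv_hat, hr_hat)`` of shape (T, B), plus the cache when
    requested.
    """
    T, B, D = X.shape
    if mask is None:
        mask = np.ones((T, B))
    mask = mask.astype(float)

    hs_f, cache_f = _lstm_direction(
        X, mask, params["W_f"], params["U_f"], params["b_f"], reverse=False
    )
    hs_b, cache_b = _lstm_direction(
        X, mask, params["W_b"], params["U_b"], params["b_b"], reverse=True
    )
    Hcat = np.concatenate([hs_f, hs_b], axis=2)  # (T, B, 2H)

    if dropout > 0.0 and rng is not None:
        keep = 1.0 - dropout
        drop_mask = (rng.random(Hcat.shape) < keep).astype(float) / keep
        Hdrop = Hcat * drop_mask
    else:
        drop_mask = None
        Hdrop = Hcat

    rv_hat = (Hdrop @ params["w_rv"])[..., 0] + params["b_rv"][0]
    hr_hat = (Hdrop @ params["w_hr"])[..., 0] + params["b_hr"][0]

    if not return_cache:
        return rv_hat, hr_hat
    cache = {
        "mask": mask,
        "cache_f": cache_f,
        "cache_b": cache_b,
        "Hdrop": Hdrop,
        "drop_mask": drop_mask,
    }
    return rv_hat, hr_hat, cache


def masked_mse(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    n = mask.sum()
    if n == 0:
        raise ValueError("all frames masked")
    return float(np.sum(mask * (pred - target) ** 2) / n)


def recon_loss(
    rv_hat: np.ndarray,
    hr_hat: np.ndarray,
    rv: np.ndarray,
    hr: np.ndarray,
    mask: np.ndarray | None = None,
    rv_mask: np.ndarray | None = None,
    hr_mask: np.ndarray | None = None,
) -> float:
    """Equal-weighted sum of per-signal mean squared errors over valid frames.

    ``mask`` applies to both signals; ``rv_mask``/``hr_mask`` refine it per
    signal (e.g. one target missing for a scan).  When one signal is fully
    masked the loss reduces to the other signal's MSE.
    """
    rv_hat = np.asarray(rv_hat, float)
    hr_hat = np.asarray(hr_hat, float)
    rv = np.asarray(rv, float)
    hr = np.asarray(hr, float)
    base = np.ones_like(rv_hat) if mask is None else np.asarray(mask, float)
    m_rv = base if rv_mask is None else base * np.asarray(rv_mask, float)
    m_hr = base if hr_mask is None else base * np.asarray(hr_mask, float)
    if m_rv.sum() == 0 and m_hr.sum() == 0:
        raise ValueError("all frames masked")
    total = 0.0
    if m_rv.sum() > 0:
        total += masked_mse(rv_hat, rv, m_rv)
    if m_hr.sum() > 0:
        total += masked_mse(hr_hat, hr, m_hr)
    return total


def loss_and_grads(
    params: BiLSTMParams,
    X: np.ndarray,
    rv: np.ndarray,
    hr: np.ndarray,
    mask: np.ndarray | None = None,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Loss and exact gradients for one padded batch.

    ``X`` is (T, B, D); ``rv``/``hr`` are (T, B) targets; ``mask`` is (T, B).
    Returns ``(loss, grads)`` with ``grads`` keyed like ``params``.
    """
    T, B, D = X.shape
    if mask is None:
        mask = np.ones((T, B))
    mask = mask.astype(float)
    rv_hat, hr_hat, cache = forward(
        params, X, mask=mask, dropout=dropout, rng=rng, return_cache=True
    )
    n = mask.sum()
    if n == 0:
        raise ValueError("all frames masked")
    loss = masked_mse(rv_hat, rv, mask) + masked_mse(hr_hat, hr, mask)

    d_rv = 2.0 * mask * (rv_hat - rv) / n  # (T, B)
    d_hr = 2.0 * mask * (hr_hat - hr) / n

    Hdrop = cache["Hdrop"]  # (T, B, 2H)
    grads = {}
    grads["w_rv"] = np.tensordot(Hdrop, d_rv, axes=([0, 1], [0, 1]))[:, None]
    grads["w_hr"] = np.tensordot(Hdrop, d_hr, axes=([0, 1], [0, 1]))[:, None]
    grads["b_rv"] = np.array([d_rv.sum()])
    grads["b_hr"] = np.array([d_hr.sum()])

    dHdrop = (
        d_rv[..., None] * params["w_rv"][:, 0]
        + d_hr[..., None] * params["w_hr"][:, 0]
    )  # (T, B, 2H)
    if cache["drop_mask"] is not None:
        dHcat = dHdrop * cache["drop_mask"]
    else:
        dHcat = dHdrop
    H = params["U_f"].shape[0]
    dhs_f = dHcat[..., :H]
    dhs_b = dHcat[..., H:]

    dW_f, dU_f, db_f, _ = _lstm_direction_backward(
        dhs_f, cache["cache_f"], params["W_f"], params["U_f"]
    )
    dW_b, dU_b, db_b, _ = _lstm_direction_backward(
        dhs_b, cache["cache_b"], params["W_b"], params["U_b"]
    )
    grads.update(
        W_f=dW_f, U_f=dU_f, b_f=db_f, W_b=dW_b, U_b=dU_b, b_b=db_b
    )
    return loss, grads


class AdamState:
    """Adam optimiser with the standard defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params: BiLSTMParams, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: BiLSTMParams, grads: BiLSTMParams) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
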