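"""Forward and backward passes of the network layers.

Everything is plain NumPy with hand-written analytic gradients; each forward
function returns a cache that its backward counterpart consumes.  The LSTM is
the peephole variant: the input and forget gates additionally see the
previous cell state (through W_ci, W_cf) and the output gate sees the current
cell state (through W_co).  The convolution is the multi-width text
convolution with a *sigmoid* activation followed by max-pooling over the
valid windows.

Masking convention: sequences are padded at the end; ``mask`` is 1.0 on real
steps and 0.0 on PAD steps.  At a PAD step the recurrent state is carried
through unchanged, so the final state equals the state at the last real
token, and appending PAD never changes any output.

For speed the input projections x_t W_x are hoisted out of the recurrence as
one matrix product, and the convolution backward touches only the windows
selected by max-pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit as sigmoid


# ---------------------------------------------------------------------------
# Peephole LSTM (one direction)
# ---------------------------------------------------------------------------


@dataclass
class LstmDirCache:
    X: np.ndarray
    mask: np.ndarray
    order: np.ndarray
    steps: list


def lstm_dir_forward(
    X: np.ndarray,
    mask: np.ndarray,
    Wx: np.ndarray,
    Wh: np.ndarray,
    Wci: np.ndarray,
    Wcf: np.ndarray,
    Wco: np.ndarray,
    b: np.ndarray,
    reverse: bool = False,
) -> tuple[np.ndarray, np.ndarray, LstmDirCache]:
    """Run one LSTM direction over X (B, T, D) -> H (B, T, H), final h.

    Gate pre-activations are computed jointly (lanes ordered i, f, g, o);
    peephole terms are added to the i/f/o lanes as the gate equations write
    them: W_ci, W_cf act on c_{t-1}, W_co on c_t.
    """
    B, T, D = X.shape
    H = Wh.shape[0]
    order = np.arange(T)[::-1] if reverse else np.arange(T)
    h = np.zeros((B, H), dtype=X.dtype)
    c = np.zeros((B, H), dtype=X.dtype)
    Hout = np.zeros((B, T, H), dtype=X.dtype)
    XW = (X.reshape(B * T, D) @ Wx + b).reshape(B, T, 4 * H)
    Wcif = np.concatenate([Wci, Wcf], axis=1)  # (H, 2H)
    steps = []
    for t in order:
        m = mask[:, t, None]
        pre = XW[:, t] + h @ Wh
        peep = c @ Wcif
        i = sigmoid(pre[:, :H] + peep[:, :H])
        f = sigmoid(pre[:, H : 2 * H] + peep[:, H:])
        g = np.tanh(pre[:, 2 * H : 3 * H])
        c_new = f * c + i * g
        o = sigmoid(pre[:, 3 * H :] + c_new @ Wco)
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        steps.append((h, c, i, f, g, o, c_new, tanh_c, m))
        c = m * c_new + (1.0 - m) * c
        h = m * h_new + (1.0 - m) * h
        Hout[:, t] = h
    return Hout, h, LstmDirCache(X=X, mask=mask, order=order, steps=steps)


def lstm_dir_backward(
    dH: np.ndarray,
    dh_final: np.ndarray | None,
    cache: LstmDirCache,
    Wx: np.ndarray,
    Wh: np.ndarray,
    Wci: np.ndarray,
    Wcf: np.ndarray,
    Wco: np.ndarray,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Backpropagate through one direction; returns dX and parameter grads."""
    X = cache.X
    B, T, D = X.shape
    Hdim = Wh.shape[0]
    g_ = {
        "Wh": np.zeros_like(Wh),
        "Wci": np.zeros_like(Wci),
        "Wcf": np.zeros_like(Wcf),
        "Wco": np.zeros_like(Wco),
    }
    dpre_all = np.zeros((B, T, 4 * Hdim), dtype=X.dtype)
    dh = np.zeros((B, Hdim), dtype=X.dtype)
    dc = np.zeros((B, Hdim), dtype=X.dtype)
    if dh_final is not None:
        dh = dh + dh_final
    for t, step in zip(cache.order[::-1], cache.steps[::-1]):
        h_prev, c_prev, i, f, g, o, c_new, tanh_c, m = step
        dh_total = dh + dH[:, t]
        dh_new = m * dh_total
        dh_prev = (1.0 - m) * dh_total
        dc_new = m * dc
        dc_prev = (1.0 - m) * dc

        do = dh_new * tanh_c
        dc_new = dc_new + dh_new * o * (1.0 - tanh_c * tanh_c)
        do_pre = do * o * (1.0 - o)
        dc_new = dc_new + do_pre @ Wco.T
        g_["Wco"] += c_new.T @ do_pre

        di_pre = dc_new * g * i * (1.0 - i)
        df_pre = dc_new * c_prev * f * (1.0 - f)
        dg_pre = dc_new * i * (1.0 - g * g)
        dc_prev = dc_prev + dc_new * f + di_pre @ Wci.T + df_pre @ Wcf.T
        g_["Wci"] += c_prev.T @ di_pre
        g_["Wcf"] += c_prev.T @ df_pre

        dpre = dpre_all[:, t]
        dpre[:, :Hdim] = di_pre
        dpre[:, Hdim : 2 * Hdim] = df_pre
        dpre[:, 2 * Hdim : 3 * Hdim] = dg_pre
        dpre[:, 3 * Hdim :] = do_pre
        g_["Wh"] += h_prev.T @ dpre
        dh = dh_prev + dpre @ Wh.T
        dc = dc_prev
    flat_dpre = dpre_all.reshape(B * T, 4 * Hdim)
    g_["Wx"] = X.reshape(B * T, D).T @ flat_dpre
    g_["b"] = flat_dpre.sum(axis=0)
    dX = (flat_dpre @ Wx.T).reshape(B, T, D)
    return dX, g_


def bilstm_forward(X, mask, params: dict, prefix: str):
    """Bidirectional pass; H concatenates forward and backward outputs."""
    Hf, hf_fin, cf = lstm_dir_forward(
        X, mask, params[f"{prefix}_f_Wx"], params[f"{prefix}_f_Wh"],
        params[f"{prefix}_f_Wci"], params[f"{prefix}_f_Wcf"],
        params[f"{prefix}_f_Wco"], params[f"{prefix}_f_b"], reverse=False,
    )
    Hb, hb_fin, cb = lstm_dir_forward(
        X, mask, params[f"{prefix}_b_Wx"], params[f"{prefix}_b_Wh"],
        params[f"{prefix}_b_Wci"], params[f"{prefix}_b_Wcf"],
        params[f"{prefix}_b_Wco"], params[f"{prefix}_b_b"], reverse=True,
    )
    H = np.concatenate([Hf, Hb], axis=2)
    return H, (hf_fin, hb_fin), (cf, cb)


def bilstm_backward(dH, dfinals, caches, params: dict, prefix: str):
    Hdim = params[f"{prefix}_f_Wh"].shape[0]
    cf, cb = caches
    dhf_fin, dhb_fin = (None, None) if dfinals is None else dfinals
    dXf, gf = lstm_dir_backward(
        dH[:, :, :Hdim], dhf_fin, cf,
        params[f"{prefix}_f_Wx"], params[f"{prefix}_f_Wh"],
        params[f"{prefix}_f_Wci"], params[f"{prefix}_f_Wcf"],
        params[f"{prefix}_f_Wco"],
    )
    dXb, gb = lstm_dir_backward(
        dH[:, :, Hdim:], dhb_fin, cb,
        params[f"{prefix}_b_Wx"], params[f"{prefix}_b_Wh"],
        params[f"{prefix}_b_Wci"], params[f"{prefix}_b_Wcf"],
        params[f"{prefix}_b_Wco"],
    )
    grads = {f"{prefix}_f_{k}": v for k, v in gf.items()}
    grads.update({f"{prefix}_b_{k}": v for k, v in gb.items()})
    return dXf + dXb, grads


# ---------------------------------------------------------------------------
# Convolution + max-pooling
# ---------------------------------------------------------------------------


@dataclass
class ConvCache:
    windows: np.ndarray  # im2col form of the input (B, J, k*d)
    S_sel: np.ndarray    # pooled sigmoid activations (B, L)
    argmax: np.ndarray   # winning window index per (B, L)
    k: int
    T: int


def conv_maxpool_forward(
    H: np.ndarray, real_lens: np.ndarray, W: np.ndarray, b: np.ndarray, k: int
) -> tuple[np.ndarray, ConvCache]:
    """One filter width: sigmoid conv over k-length windows, then max-pool.

    Valid windows are those lying inside the real (un-padded) sequence; a
    sentence shorter than k keeps its single left-aligned padded window so
    the pool is never empty.  n real steps with n >= k give n - k + 1
    windows.
    """
    B, T, d = H.shape
    if T < k:
        raise ValueError(f"sequence length {T} shorter than filter width {k}")
    J = T - k + 1
    win = np.lib.stride_tricks.sliding_window_view(H, k, axis=1)  # (B,J,d,k)
    win = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, J, k * d)
    S = sigmoid(win.reshape(B * J, k * d) @ W + b).reshape(B, J, -1)
    n_valid = np.maximum(real_lens - k + 1, 1)  # (B,)
    valid = np.arange(J)[None, :] < n_valid[:, None]
    masked = np.where(valid[:, :, None], S, -1.0)
    argmax = masked.argmax(axis=1)  # (B, L)
    pooled = np.take_along_axis(S, argmax[:, None, :], axis=1)[:, 0, :]
    return pooled, ConvCache(windows=win, S_sel=pooled, argmax=argmax, k=k, T=T)


def conv_maxpool_backward(
    dpooled: np.ndarray, cache: ConvCache, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (dH, dW, db); only the argmax windows carry gradient.

    The per-window gradient is scattered into a (B, J, L) tensor — one
    nonzero per (sample, filter), so plain overwrite is collision-free —
    and both dW and dH then reduce to dense matrix products.
    """
    B, J, kd = cache.windows.shape
    k, T = cache.k, cache.T
    d = kd // k
    S = cache.S_sel
    dpre_sel = (dpooled * S * (1.0 - S)).astype(cache.windows.dtype)  # (B, L)
    P = np.zeros((B, J, dpre_sel.shape[1]), dtype=cache.windows.dtype)
    np.put_along_axis(P, cache.argmax[:, None, :], dpre_sel[:, None, :], axis=1)
    flat_win = cache.windows.reshape(B * J, kd)
    flat_P = P.reshape(B * J, -1)
    dW = flat_win.T @ flat_P
    db = dpre_sel.sum(axis=0)
    dwin = (flat_P @ W.T).reshape(B, J, k, d)
    dH = np.zeros((B, T, d), dtype=cache.windows.dtype)
    for i in range(k):
        dH[:, i : i + J] += dwin[:, :, i]
    return dH, dW, db


# ---------------------------------------------------------------------------
# Output layer
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def output_forward(A: np.ndarray, Wo: np.ndarray, bo: np.ndarray) -> np.ndarray:
    return softmax(A @ Wo + bo)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    eps = np.finfo(probs.dtype).tiny
    return float(-np.mean(np.log(probs[np.arange(len(labels)), labels] + eps)))


def output_backward(
    A: np.ndarray, probs: np.ndarray, labels: np.ndarray, Wo: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradient of mean cross-entropy; returns (dA, dWo, dbo)."""
    B = A.shape[0]
    dlogits = probs.astype(A.dtype).copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits /= B
    dWo = A.T @ dlogits
    dbo = dlogits.sum(axis=0)
    dA = dlogits @ Wo.T
    return dA, dWo, dbo
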