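"""Independent reference implementations used as test oracles.

Deliberately written as plain Python loops over the printed gate/filter
formulas, sharing no code with the package's vectorized implementations.
"""

from __future__ import annotations

import math


def ref_sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def ref_lstm_step(x, h_prev, c_prev, W):
    """One peephole LSTM step on plain lists; W is a dict of list matrices.

    i_t = s(Wxi x + Whi h + Wci c_prev + bi)
    f_t = s(Wxf x + Whf h + Wcf c_prev + bf)
    c_t = f_t*c_prev + i_t*tanh(Wxc x + Whc h + bc)
    o_t = s(Wxo x + Who h + Wco c_t + bo)
    h_t = o_t*tanh(c_t)
    """

    def mv(M, v):  # M: (n_in, n_out) row-major like the package's weights
        n_out = len(M[0])
        return [sum(v[i] * M[i][j] for i in range(len(v))) for j in range(n_out)]

    def add(*vs):
        return [sum(t) for t in zip(*vs)]

    H = len(h_prev)
    i = [ref_sigmoid(v) for v in add(mv(W["Wxi"], x), mv(W["Whi"], h_prev),
                                     mv(W["Wci"], c_prev), W["bi"])]
    f = [ref_sigmoid(v) for v in add(mv(W["Wxf"], x), mv(W["Whf"], h_prev),
                                     mv(W["Wcf"], c_prev), W["bf"])]
    g = [math.tanh(v) for v in add(mv(W["Wxc"], x), mv(W["Whc"], h_prev),
                                   W["bc"])]
    c = [f[j] * c_prev[j] + i[j] * g[j] for j in range(H)]
    o = [ref_sigmoid(v) for v in add(mv(W["Wxo"], x), mv(W["Who"], h_prev),
                                     mv(W["Wco"], c), W["bo"])]
    h = [o[j] * math.tanh(c[j]) for j in range(H)]
    return h, c


def ref_lstm_sequence(X, W, H_size):
    h = [0.0] * H_size
    c = [0.0] * H_size
    out = []
    for x in X:
        h, c = ref_lstm_step(list(x), h, c, W)
        out.append(h)
    return out


def split_joint_weights(Wx, Wh, Wci, Wcf, Wco, b):
    """Split the package's joint i|f|g|o weight layout into per-gate lists."""
    H = len(Wci)

    def cols(M, lo, hi):
        return [list(row[lo:hi]) for row in M]

    return {
        "Wxi": cols(Wx, 0, H), "Wxf": cols(Wx, H, 2 * H),
        "Wxc": cols(Wx, 2 * H, 3 * H), "Wxo": cols(Wx, 3 * H, 4 * H),
        "Whi": cols(Wh, 0, H), "Whf": cols(Wh, H, 2 * H),
        "Whc": cols(Wh, 2 * H, 3 * H), "Who": cols(Wh, 3 * H, 4 * H),
        "Wci": [list(r) for r in Wci], "Wcf": [list(r) for r in Wcf],
        "Wco": [list(r) for r in Wco],
        "bi": list(b[0:H]), "bf": list(b[H : 2 * H]),
        "bc": list(b[2 * H : 3 * H]), "bo": list(b[3 * H : 4 * H]),
    }


def ref_conv_maxpool(H, W, b, k):
    """Brute-force sigmoid convolution + max-pool for one filter bank.

    H: (n, d) list of rows; W: (k*d, L); returns list of L pooled values.
    """
    n = len(H)
    L = len(W[0])
    pooled = []
    for l in range(L):
        feats = []
        for j in range(n - k + 1):
            window = [v for row in H[j : j + k] for v in row]
            feats.append(
                ref_sigmoid(sum(window[i] * W[i][l] for i in range(len(window)))
                            + b[l])
            )
        pooled.append(max(feats))
    return pooled


def ref_softmax(values):
    m = max(values)
    exps = [math.exp(v - m) for v in values]
    s = sum(exps)
    return [e / s for e in exps]


def ref_micro_prf(gold, predicted, none_label):
    """Confusion-count micro P/R/F1 excluding the NONE label."""
    correct = sum(
        1 for g, p in zip(gold, predicted) if g == p and g != none_label
    )
    n_pred = sum(1 for p in predicted if p != none_label)
    n_gold = sum(1 for g in gold if g != none_label)
    p = correct / n_pred if n_pred else 0.0
    r = correct / n_gold if n_gold else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f
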