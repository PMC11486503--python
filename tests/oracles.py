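"""Independent explicit-loop reference implementations.

Straight-line scalar code, written without any of the package's tensor
machinery, used to pin down the expected values of every numeric operation
on hand-sized inputs.
"""

import math

import numpy as np


def softmax_row(row):
    m = max(row)
    exps = [math.exp(v - m) for v in row]
    total = sum(exps)
    return [e / total for e in exps]


def gin_layer(h, adj, mlp_fn):
    """h: N x d list-of-lists; adj: N x N; mlp_fn maps one vector to one vector."""
    n = len(h)
    out = []
    for i in range(n):
        neigh = [0.0] * len(h[0])
        for j in range(n):
            if adj[i][j]:
                for k in range(len(h[0])):
                    neigh[k] += h[j][k]
        trans = mlp_fn(neigh)
        out.append([h[i][k] + trans[k] for k in range(len(trans))])
    return out


def affine(x, w, b=None):
    out = [sum(x[i] * w[i][j] for i in range(len(x))) for j in range(len(w[0]))]
    if b is not None:
        out = [o + bb for o, bb in zip(out, b)]
    return out


def mlp(x, weights, biases):
    """Affine chain with ReLU between layers (none after the last)."""
    for idx, (w, b) in enumerate(zip(weights, biases)):
        x = affine(x, w, b)
        if idx < len(weights) - 1:
            x = [max(0.0, v) for v in x]
    return x


def self_attend(h, q0, wq, wk, wv, wo, scale):
    """Returns (attention M x N, representative vectors M x d)."""
    q = [affine(row, wq) for row in q0]
    k = [affine(row, wk) for row in h]
    v = [affine(row, wv) for row in h]
    attn = []
    for qi in q:
        logits = [sum(a * b for a, b in zip(qi, kj)) / scale for kj in k]
        attn.append(softmax_row(logits))
    rep = []
    for m, qi in enumerate(q):
        mix = [
            qi[c] + sum(attn[m][j] * v[j][c] for j in range(len(v)))
            for c in range(len(qi))
        ]
        rep.append([max(0.0, val) for val in affine(mix, wo)])
    return attn, rep


def cosine_matrix(rep_a, rep_b):
    out = []
    for za in rep_a:
        row = []
        na = math.sqrt(sum(v * v for v in za))
        for zb in rep_b:
            nb = math.sqrt(sum(v * v for v in zb))
            dot = sum(a * b for a, b in zip(za, zb))
            row.append(0.0 if na == 0.0 or nb == 0.0 else dot / (na * nb))
        out.append(row)
    return out


def cross_attend(q, k, v, lam, wo, scale):
    """Returns (raw attention, mask, output) for one attention direction."""
    raw, mask, out = [], [], []
    for qi in q:
        logits = [sum(a * b for a, b in zip(qi, kj)) / scale for kj in k]
        weights = softmax_row(logits)
        raw.append(weights)
        mask.append([1.0 if w >= lam else 0.0 for w in weights])
    for m, qi in enumerate(q):
        mix = [
            qi[c]
            + sum(raw[m][j] * mask[m][j] * v[j][c] for j in range(len(v)))
            for c in range(len(qi))
        ]
        out.append([max(0.0, val) for val in affine(mix, wo)])
    return raw, mask, out


def pool_and_standardize(o, eps=1e-6):
    m_rows = len(o)
    d = len(o[0])
    pooled = [sum(o[m][c] for m in range(m_rows)) / m_rows for c in range(d)]
    mu = sum(pooled) / d
    var = sum((v - mu) ** 2 for v in pooled) / d
    return [(v - mu) / (math.sqrt(var) + eps) for v in pooled]


def bce(logits, labels):
    total = 0.0
    for z, y in zip(logits, labels):
        p = 1.0 / (1.0 + math.exp(-z))
        total += -(y * math.log(p) + (1 - y) * math.log(1 - p))
    return total / len(logits)


def auroc(labels, scores):
    """Concordant-pair counting with 0.5 credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        raise ValueError("both classes required")
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def tensor_weights(linear):
    """Pull a package Linear's weights into plain lists for the oracles."""
    w = linear.weight.data.tolist()
    b = linear.bias.data.reshape(-1).tolist() if linear.bias is not None else None
    return w, b


def mlp_weights(package_mlp):
    weights, biases = [], []
    for layer in package_mlp.layers:
        w, b = tensor_weights(layer)
        weights.append(w)
        biases.append(b)
    return weights, biases


def as_lists(arr):
    return np.asarray(arr).tolist()
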