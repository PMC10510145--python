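"""Independent scalar-loop reference implementations used as test oracles.

Everything here is written with explicit Python loops over floats and
plain lists, deliberately sharing no code path with the package: the
message-passing recurrence, the concordance index, 1-D convolution,
the GRU recurrence, softmax cross-entropy and central finite
differences.
"""

from __future__ import annotations

import math

import numpy as np


# --------------------------------------------------------------- CMPNN oracle
def _relu(v):
    return [x if x > 0 else 0.0 for x in v]


def _affine(row, W, b):
    d_out = len(W[0])
    return [sum(row[i] * W[i][j] for i in range(len(row))) + b[j]
            for j in range(d_out)]


def _pool(hidden_rows):
    """max ⊙ sum over a list of vectors; [] pools to zeros."""
    if not hidden_rows:
        return None
    d = len(hidden_rows[0])
    out = []
    for j in range(d):
        col = [r[j] for r in hidden_rows]
        out.append(max(col) * sum(col))
    return out


def cmpnn_scalar(graph, weights, depth):
    """Scalar-loop undirected message passing + communicate/sum readout.

    ``weights``: dict with keys aW, ab, bW, bb (init affines),
    W (list of per-layer square matrices), cW, cb (communicate map),
    all as nested Python lists. Returns the molecule embedding list.
    """
    d = len(weights["ab"])
    x_v = graph.atom_features.tolist()
    x_e = graph.bond_features.tolist()
    h_v = [_relu(_affine(r, weights["aW"], weights["ab"])) for r in x_v]
    h_e = [_relu(_affine(r, weights["bW"], weights["bb"])) for r in x_e]
    zeros = [0.0] * d
    h_ev = [zeros[:] for _ in range(graph.n_atoms)]
    h_vv = [zeros[:] for _ in range(graph.n_atoms)]
    for layer in range(depth):
        new_h_v = []
        for v in range(graph.n_atoms):
            f_ev = _pool([h_e[e] for e in sorted(graph.incident_bonds[v])]) or zeros
            f_vv = _pool([h_v[u] for u in sorted(graph.atom_neighbors[v])]) or zeros
            h_ev[v] = [h_v[v][j] * f_ev[j] for j in range(d)]
            h_vv[v] = [h_v[v][j] * f_vv[j] for j in range(d)]
            new_h_v.append([h_ev[v][j] + h_vv[v][j] + h_v[v][j]
                            for j in range(d)])
        new_h_e = []
        for e in range(graph.n_bonds):
            f_ee = _pool([h_e[o] for o in sorted(graph.bond_neighbors[e])]) or zeros
            h_ee = [h_e[e][j] * f_ee[j] for j in range(d)]
            W = weights["W"][layer]
            pre = [sum(h_ee[i] * W[i][j] for i in range(d)) + h_e[e][j]
                   for j in range(d)]
            new_h_e.append(_relu(pre))
        h_v, h_e = new_h_v, new_h_e
    pooled = [0.0] * d
    for v in range(graph.n_atoms):
        cat = h_v[v] + h_vv[v] + h_ev[v]
        out = _relu(_affine(cat, weights["cW"], weights["cb"]))
        pooled = [pooled[j] + out[j] for j in range(d)]
    return pooled


def encoder_weights_as_lists(enc) -> dict:
    """Extract a MolEncoder's parameters into plain nested lists."""
    return {
        "aW": enc.init_linear_atom.W.data.tolist(),
        "ab": enc.init_linear_atom.b.data.tolist(),
        "bW": enc.init_linear_bond.W.data.tolist(),
        "bb": enc.init_linear_bond.b.data.tolist(),
        "W": [w.data.tolist() for w in enc.bond_update_weight],
        "cW": enc.communicate_map.W.data.tolist(),
        "cb": enc.communicate_map.b.data.tolist(),
    }


# ------------------------------------------------------- concordance index
def ci_brute_force(predictions, labels) -> float:
    num, z = 0.0, 0
    n = len(labels)
    for i in range(n):
        for j in range(n):
            if labels[i] > labels[j]:
                z += 1
                diff = predictions[i] - predictions[j]
                num += 1.0 if diff > 0 else (0.5 if diff == 0 else 0.0)
    if z == 0:
        raise ZeroDivisionError("no strictly ordered pair")
    return num / z


# ----------------------------------------------------------- sequence oracles
def conv1d_scalar(x, W, b, k):
    """Valid 1-D convolution of one segment: x [L][c_in], W [k*c_in][c_out]."""
    L, c_in = len(x), len(x[0])
    c_out = len(b)
    out = []
    for t in range(L - k + 1):
        window = [x[t + dt][i] for dt in range(k) for i in range(c_in)]
        out.append([sum(window[m] * W[m][j] for m in range(len(window))) + b[j]
                    for j in range(c_out)])
    return out


def gru_scalar(x, weights):
    """Step-by-step GRU recurrence; weights from a GRU module as lists."""

    def sig(v):
        return 1.0 / (1.0 + math.exp(-v))

    def mat(v, M):
        return [sum(v[i] * M[i][j] for i in range(len(v)))
                for j in range(len(M[0]))]

    d = len(weights["bz"])
    h = [0.0] * d
    out = []
    for xt in x:
        z = [sig(a + b + c) for a, b, c in
             zip(mat(xt, weights["Wz"]), mat(h, weights["Uz"]), weights["bz"])]
        r = [sig(a + b + c) for a, b, c in
             zip(mat(xt, weights["Wr"]), mat(h, weights["Ur"]), weights["br"])]
        rh = [r[j] * h[j] for j in range(d)]
        n = [math.tanh(a + b + c) for a, b, c in
             zip(mat(xt, weights["Wn"]), mat(rh, weights["Un"]), weights["bn"])]
        h = [(1 - z[j]) * n[j] + z[j] * h[j] for j in range(d)]
        out.append(h[:])
    return out


def softmax_xent_scalar(logits, true_index) -> float:
    m = max(logits)
    exps = [math.exp(v - m) for v in logits]
    total = sum(exps)
    return -math.log(exps[true_index] / total)


# ----------------------------------------------------------- finite difference
def finite_difference_grads(f, tensors, eps: float = 1e-6):
    """Central-difference gradients of scalar f() w.r.t. each Tensor's data."""
    grads = []
    for t in tensors:
        g = np.zeros_like(t.data)
        flat = t.data.reshape(-1)
        gflat = g.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            up = f()
            flat[i] = orig - eps
            down = f()
            flat[i] = orig
            gflat[i] = (up - down) / (2 * eps)
        grads.append(g)
    return grads


def max_relative_error(a: np.ndarray, b: np.ndarray, floor: float = 1e-6):
    """max |a-b| / max(|a|, |b|, floor), elementwise."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    denom = np.maximum(np.maximum(np.abs(a), np.abs(b)), floor)
    return float(np.max(np.abs(a - b) / denom))
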