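"""Independent scalar re-implementations used as test oracles.

Everything here is written with plain Python loops directly from the
defining formulas (PRR/CI, cross-entropies, attention softmaxes, windowed
convolution, rank-based AUC, threshold-sweep average precision, and a full
from-scratch forward pass of the network reading the model's weights).
Nothing imports the code paths under test except to read weight arrays.
"""

import math

import numpy as np


# -- PRR / CI ----------------------------------------------------------------

def prr_oracle(a, b, c, d):
    prr = (a / b) / ((c - a) / (d - b))
    se = math.sqrt(1 / a - 1 / b + 1 / (c - a) + 1 / (d - b))
    lo = math.exp(math.log(prr) - 1.96 * se)
    hi = math.exp(math.log(prr) + 1.96 * se)
    return prr, se, lo, hi


# -- losses ------------------------------------------------------------------

def bce_oracle(y_true, y_pred, eps=1e-7):
    total = 0.0
    for t, p in zip(y_true, y_pred):
        p = min(max(p, eps), 1 - eps)
        total += t * math.log(p) + (1 - t) * math.log(1 - p)
    return -total / len(y_true)


def severity_oracle(class_true, class_pred, mask=None, eps=1e-7):
    total, count = 0.0, 0
    for i in range(len(class_true)):
        if mask is not None and not mask[i]:
            continue
        for j in range(len(class_true[i])):
            p = min(max(class_pred[i][j], eps), 1 - eps)
            t = class_true[i][j]
            total += t * math.log(p) + (1 - t) * math.log(1 - p)
            count += 1
    return 0.0 if count == 0 else -total / count


# -- ranking metrics ----------------------------------------------------------

def auc_bruteforce(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def aupr_threshold_sweep(scores, labels):
    """Average precision: sum of (delta recall) * precision at each threshold."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    labels = np.asarray(labels)[order]
    n_pos = labels.sum()
    tp = fp = 0
    ap = 0.0
    prev_recall = 0.0
    scores_sorted = np.asarray(scores)[order]
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and scores_sorted[j] == scores_sorted[i]:
            j += 1
        tp += labels[i:j].sum()
        fp += (j - i) - labels[i:j].sum()
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


# -- network forward pass ------------------------------------------------------

def _linear(layer, x):
    return np.asarray(x) @ layer.weight.data + layer.bias.data


def _gru(cell, x, h):
    xh = np.concatenate([x, h], axis=-1)
    z = 1 / (1 + np.exp(-_linear(cell.w_z, xh)))
    r = 1 / (1 + np.exp(-_linear(cell.w_r, xh)))
    n = np.tanh(_linear(cell.w_n, np.concatenate([x, r * h], axis=-1)))
    return (1 - z) * n + z * h


def _relu(x):
    return np.maximum(x, 0.0)


def _softmax(v):
    e = np.exp(v - np.max(v))
    return e / e.sum()


def mga_oracle(mga, graph):
    """Loop transcription of the three attention stages + GRU updates."""
    H = _relu(_linear(mga.atom_proj, graph.atom_features))
    A = graph.n_atoms
    if graph.n_bonds > 0:
        E = _relu(_linear(mga.bond_proj, graph.bond_features))
        for attn, feats_of in [(a, "edge") for a in mga.edge_attn] + [
            (a, "nbr") for a in mga.nbr_attn
        ]:
            gru = mga.edge_gru if feats_of == "edge" else mga.nbr_gru
            h0 = np.zeros_like(H)
            seen = []
            for i in range(A):
                inc = graph.incidence[i]
                if not inc:
                    continue
                seen.append(i)
                if feats_of == "edge":
                    feats = [E[b] for b in inc]
                else:
                    feats = [H[j] for j in graph.neighbors[i]]
                z = [
                    _relu(_linear(attn, np.concatenate([H[i], f])))[0] for f in feats
                ]
                alpha = _softmax(np.array(z))
                h0[i] = _relu(sum(a * f for a, f in zip(alpha, feats)))
            H_new = _gru(gru, h0, H)
            for i in seen:
                H[i] = H_new[i]
    s = H.sum(axis=0, keepdims=True)
    for attn in mga.super_attn:
        z = np.array(
            [_relu(_linear(attn, np.concatenate([s[0], H[i]])))[0] for i in range(A)]
        )
        alpha = _softmax(z)
        agg = _relu((alpha[:, None] * H).sum(axis=0, keepdims=True))
        s = _gru(mga.super_gru, agg, s)
    return _linear(mga.out_fc, s)


def conv_same_oracle(weight, bias, x, h):
    """Windowed Eq-7 convolution: c_t = relu later; returns pre-activation."""
    L, C = x.shape
    p = (h - 1) // 2
    xp = np.vstack([np.zeros((p, C)), x, np.zeros((p, C))])
    out = np.zeros((L, weight.shape[1]))
    for t in range(L):
        window = xp[t : t + h].reshape(-1)  # h rows, offset-major then channel
        out[t] = window @ weight + bias
    return out


def cnn_oracle(cnn, onehot):
    x = onehot @ cnn.embedding.data
    for bank in cnn.layers:
        maps = np.concatenate(
            [
                _relu(conv_same_oracle(c.weight.data, c.bias.data, x, c.kernel_size))
                for c in bank
            ],
            axis=1,
        )
        x = maps + x
    return x.max(axis=0)


def fusion_oracle(fusion, M):
    """Scaled dot-product multi-head self-attention, scalar transcription."""
    outs = []
    scale = math.sqrt(fusion.head_dim)
    for wq, wk, wv in zip(fusion.w_q, fusion.w_k, fusion.w_v):
        Q, K, V = M @ wq.data, M @ wk.data, M @ wv.data
        scores = Q @ K.T
        att = np.zeros_like(scores)
        for r in range(scores.shape[0]):
            if fusion.cfg.literal_eq9:
                att[r] = _softmax(scores[r])
            else:
                att[r] = _softmax(scores[r] / scale)
        if fusion.cfg.literal_eq9:
            att = att / scale
        outs.append(att @ V)
    fused = np.concatenate(outs, axis=1)
    if fusion.cfg.fusion_pool == "mean":
        return fused.mean(axis=0)
    return fused.max(axis=0)


def forward_oracle(model, pair):
    """Full end-to-end forward pass for one pair, loops only."""
    graph_vec = mga_oracle(model.mga, pair.graph)[0]
    cnn_vec = cnn_oracle(model.cnn, pair.smiles_onehot)
    reps = [
        _relu(_linear(model.proj_graph, graph_vec)),
        _relu(_linear(model.proj_cnn, cnn_vec)),
        _relu(_linear(model.proj_drug_int, pair.drug_row_int)),
        _relu(_linear(model.proj_drug_ser, pair.drug_row_ser)),
        _relu(_linear(model.proj_semantic, pair.adr_semantic)),
        _relu(_linear(model.proj_adr_int, pair.adr_col_int)),
        _relu(_linear(model.proj_adr_ser, pair.adr_col_ser)),
    ]
    M = np.stack(reps)
    joint = fusion_oracle(model.fusion, M)

    def head(mlp, x):
        hidden = _relu(_linear(mlp.fc1, x))
        return 1 / (1 + np.exp(-_linear(mlp.fc2, hidden)))

    return head(model.head_association, joint), head(model.head_severity, joint)
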