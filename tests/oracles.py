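"""Independent brute-force oracles used by the tests.

Every function here re-computes a block's output with explicit Python
loops and plain numpy, reading only the parameter arrays of the module
under test — no code path is shared with the package's vectorized
implementations.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf


def softmax_rows(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def gelu(x: np.ndarray) -> np.ndarray:
    return x * 0.5 * (1.0 + erf(x / math.sqrt(2.0)))


def mha_oracle(
    q_tokens: np.ndarray,
    k_tokens: np.ndarray,
    v_tokens: np.ndarray,
    num_heads: int,
    w_proj: np.ndarray,
    b_proj: np.ndarray,
    mask: np.ndarray | None = None,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Loop-based multi-head scaled-dot-product attention.

    ``q_tokens``/``k_tokens``/``v_tokens`` are already-projected per-head
    arrays ``(nW, heads, T, hd)``; ``mask`` is additive ``(nW, T, T)``;
    ``bias`` additive ``(heads, T, T)``.  Returns ``(nW, T, C)`` after
    the output projection ``w_proj`` (C×C) and ``b_proj``.
    """
    nw, nh, t, hd = q_tokens.shape
    heads_out = np.zeros((nw, nh, t, hd))
    for w in range(nw):
        for h in range(nh):
            for i in range(t):
                scores = np.empty(t)
                for j in range(t):
                    scores[j] = q_tokens[w, h, i] @ k_tokens[w, h, j] / math.sqrt(hd)
                    if bias is not None:
                        scores[j] += bias[h, i, j]
                    if mask is not None:
                        scores[j] += mask[w, i, j]
                weights = softmax_rows(scores)
                heads_out[w, h, i] = sum(
                    weights[j] * v_tokens[w, h, j] for j in range(t)
                )
    merged = heads_out.transpose(0, 2, 1, 3).reshape(nw, t, nh * hd)
    return merged @ w_proj.T + b_proj


def dwc_oracle(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Depth-wise conv, zero padding k//2, explicit 6-deep loops."""
    c, d, h, w = x.shape
    k = weight.shape[1]
    p = k // 2
    out = np.zeros_like(x)
    for ch in range(c):
        for z in range(d):
            for y in range(h):
                for xx in range(w):
                    acc = 0.0
                    for i in range(k):
                        for j in range(k):
                            for l in range(k):
                                zz, yy, ww = z + i - p, y + j - p, xx + l - p
                                if 0 <= zz < d and 0 <= yy < h and 0 <= ww < w:
                                    acc += x[ch, zz, yy, ww] * weight[ch, i, j, l]
                    out[ch, z, y, xx] = acc + bias[ch]
    return out


def conv1_oracle(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Pointwise channel-mixing conv with explicit loops."""
    c_out, c_in = weight.shape
    out = np.zeros((c_out,) + x.shape[1:])
    for co in range(c_out):
        for ci in range(c_in):
            out[co] += weight[co, ci] * x[ci]
        out[co] += bias[co]
    return out


def gate_oracle(x: np.ndarray, gate) -> np.ndarray:
    """sigmoid(FL(ReLU(FL(AP(x))))) from the gate's parameter arrays."""
    pooled = x.mean(axis=(1, 2, 3))
    h = gate.fc1.weight.data @ pooled + gate.fc1.bias.data
    h = np.maximum(h, 0.0)
    h = gate.fc2.weight.data @ h + gate.fc2.bias.data
    return 1.0 / (1.0 + np.exp(-h))


def ecsa_oracle(x: np.ndarray, block) -> np.ndarray:
    """Direct evaluation of the ECSA equations from the block's params."""
    c = x.shape[0]
    flx_q = conv1_oracle(x, block.fl_q.weight.data, block.fl_q.bias.data)
    flx_k = conv1_oracle(x, block.fl_k.weight.data, block.fl_k.bias.data)
    qw = gate_oracle(flx_q, block.gate_q)
    kw = gate_oracle(flx_k, block.gate_k)
    vw = gate_oracle(x, block.gate_v)
    qp = flx_q * qw.reshape(c, 1, 1, 1)
    kp = flx_k * kw.reshape(c, 1, 1, 1)
    vp = x * vw.reshape(c, 1, 1, 1)
    local = dwc_oracle(kp * qp, block.dwc.weight.data, block.dwc.bias.data)
    local = conv1_oracle(local, block.conv.weight.data, block.conv.bias.data)
    # channel softmax at every voxel
    attn = np.zeros_like(local)
    for z in range(x.shape[1]):
        for y in range(x.shape[2]):
            for xx in range(x.shape[3]):
                attn[:, z, y, xx] = softmax_rows(local[:, z, y, xx])
    return conv1_oracle(attn * vp, block.fl_out.weight.data, block.fl_out.bias.data)


def layernorm_oracle(vec: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                     eps: float = 1e-5) -> np.ndarray:
    mu = vec.mean()
    var = ((vec - mu) ** 2).mean()
    return (vec - mu) / math.sqrt(var + eps) * gamma + beta


def mlp_oracle(vec: np.ndarray, mlp) -> np.ndarray:
    h = gelu(mlp.fc1.weight.data @ vec + mlp.fc1.bias.data)
    return mlp.fc2.weight.data @ h + mlp.fc2.bias.data


def enhanced_transformer_oracle(x: np.ndarray, block) -> np.ndarray:
    """y = ECSA(LN(x)) + x; z = y + MLP(LN(y)) with per-voxel LN/MLP loops."""
    c, d, h, w = x.shape
    lnx = np.zeros_like(x)
    for z in range(d):
        for y in range(h):
            for xx in range(w):
                lnx[:, z, y, xx] = layernorm_oracle(
                    x[:, z, y, xx], block.norm1.gamma.data, block.norm1.beta.data
                )
    mid = ecsa_oracle(lnx, block.ecsa) + x
    out = np.zeros_like(mid)
    for z in range(d):
        for y in range(h):
            for xx in range(w):
                vec = mid[:, z, y, xx]
                normed = layernorm_oracle(
                    vec, block.norm2.gamma.data, block.norm2.beta.data
                )
                out[:, z, y, xx] = vec + mlp_oracle(normed, block.mlp)
    return out


def groupnorm_oracle(x: np.ndarray, groups: int, gamma: np.ndarray,
                     beta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    c = x.shape[0]
    per = c // groups
    out = np.zeros_like(x)
    for g in range(groups):
        sl = slice(g * per, (g + 1) * per)
        vals = x[sl]
        mu, var = vals.mean(), vals.var()
        out[sl] = (vals - mu) / math.sqrt(var + eps)
    return out * gamma.reshape(c, 1, 1, 1) + beta.reshape(c, 1, 1, 1)


def _unit_oracle(x: np.ndarray, unit) -> np.ndarray:
    norm = unit.norm
    if hasattr(norm, "groups"):
        out = groupnorm_oracle(x, norm.groups, norm.gamma.data, norm.beta.data)
    else:  # per-channel normalization over the sample
        c = x.shape[0]
        out = np.zeros_like(x)
        for ch in range(c):
            mu, var = x[ch].mean(), x[ch].var()
            out[ch] = (x[ch] - mu) / math.sqrt(var + 1e-5)
        out = (
            out * norm.gamma.data.reshape(c, 1, 1, 1)
            + norm.beta.data.reshape(c, 1, 1, 1)
        )
    if unit.activation == "gelu":
        return gelu(out)
    if unit.activation == "relu":
        return np.maximum(out, 0.0)
    return out


def gns_oracle(x: np.ndarray, block) -> np.ndarray:
    """Split → conv/DWC/conv branch with units → concat → shuffle, by loops."""
    c = x.shape[0]
    left, right = x[: c // 2], x[c // 2 :]
    right = _unit_oracle(
        conv1_oracle(right, block.conv1.weight.data, block.conv1.bias.data),
        block.unit1,
    )
    right = _unit_oracle(
        dwc_oracle(right, block.dwc.weight.data, block.dwc.bias.data), block.unit2
    )
    right = _unit_oracle(
        conv1_oracle(right, block.conv2.weight.data, block.conv2.bias.data),
        block.unit3,
    )
    cat = np.concatenate([left, right], axis=0)
    g = block.shuffle_groups
    perm = np.arange(c).reshape(g, c // g).T.reshape(-1)
    return cat[perm]


def hd95_oracle(pred: np.ndarray, truth: np.ndarray, spacing=(1.0, 1.0, 1.0)):
    """All-pairs boundary distance / percentile computation."""
    def boundary(mask):
        pts = []
        d, h, w = mask.shape
        for z in range(d):
            for y in range(h):
                for x in range(w):
                    if not mask[z, y, x]:
                        continue
                    for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                       (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                        zz, yy, xx = z + dz, y + dy, x + dx
                        if not (0 <= zz < d and 0 <= yy < h and 0 <= xx < w) or \
                                not mask[zz, yy, xx]:
                            pts.append((z, y, x))
                            break
        return np.array(pts, dtype=float) * np.asarray(spacing)

    bp, bt = boundary(pred), boundary(truth)
    if len(bp) == 0 or len(bt) == 0:
        return float("nan")
    d_pt = [min(np.linalg.norm(p - t) for t in bt) for p in bp]
    d_tp = [min(np.linalg.norm(t - p) for p in bp) for t in bt]
    return max(np.percentile(d_pt, 95.0), np.percentile(d_tp, 95.0))
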