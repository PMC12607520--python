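"""Independent straight-line re-implementations used as test oracles.

Everything here is plain numpy written directly from the block equations —
explicit loops for convolution, no im2col, no autograd — so agreement with
the package's forward passes is a genuine dual-route check.
"""

from __future__ import annotations

import numpy as np


def same_pad_amounts(size, kernel, stride):
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    return total // 2, total - total // 2


def conv2d_ref(x, w, b=None, stride=1, groups=1, pad_value=0.0):
    """Naive grouped cross-correlation with 'same' padding, (N,C,H,W)."""
    N, C, H, W = x.shape
    K, Cg, kh, kw = w.shape
    Kg = K // groups
    pt, pb = same_pad_amounts(H, kh, stride)
    pl, pr = same_pad_amounts(W, kw, stride)
    xp = np.full((N, C, H + pt + pb, W + pl + pr), pad_value)
    xp[:, :, pt : pt + H, pl : pl + W] = x
    OH = (xp.shape[2] - kh) // stride + 1
    OW = (xp.shape[3] - kw) // stride + 1
    out = np.zeros((N, K, OH, OW))
    for k in range(K):
        g = k // Kg
        cs = slice(g * Cg, (g + 1) * Cg)
        for i in range(OH):
            for j in range(OW):
                patch = xp[:, cs, i * stride : i * stride + kh,
                           j * stride : j * stride + kw]
                out[:, k, i, j] = (patch * w[k]).sum(axis=(1, 2, 3))
        if b is not None:
            out[:, k] += b[k]
    return out


def bn_train_ref(x, gamma, beta, eps=1e-5):
    mu = x.mean(axis=(0, 2, 3), keepdims=True)
    var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
    xhat = (x - mu) / np.sqrt(var + eps)
    return xhat * gamma.reshape(1, -1, 1, 1) + beta.reshape(1, -1, 1, 1)


def max_pool_ref(x, kernel=3, stride=2):
    N, C, H, W = x.shape
    pt, pb = same_pad_amounts(H, kernel, stride)
    pl, pr = same_pad_amounts(W, kernel, stride)
    xp = np.full((N, C, H + pt + pb, W + pl + pr), -np.inf)
    xp[:, :, pt : pt + H, pl : pl + W] = x
    OH = (xp.shape[2] - kernel) // stride + 1
    OW = (xp.shape[3] - kernel) // stride + 1
    out = np.zeros((N, C, OH, OW))
    for i in range(OH):
        for j in range(OW):
            out[:, :, i, j] = xp[:, :, i * stride : i * stride + kernel,
                                 j * stride : j * stride + kernel].max(axis=(2, 3))
    return out


def avg_pool_ref(x, kernel=2):
    N, C, H, W = x.shape
    OH, OW = H // kernel, W // kernel
    out = np.zeros((N, C, OH, OW))
    for i in range(OH):
        for j in range(OW):
            out[:, :, i, j] = x[:, :, i * kernel : (i + 1) * kernel,
                                j * kernel : (j + 1) * kernel].mean(axis=(2, 3))
    return out


def sigmoid_ref(x):
    return 1.0 / (1.0 + np.exp(-x))


def relu_ref(x):
    return np.maximum(x, 0.0)


# -- block-level oracles (weights extracted from the package's modules) ------


def _bias(conv):
    return None if conv.bias is None else conv.bias.data


def stem_ref(stem, x):
    z = conv2d_ref(x, stem.conv.weight.data, _bias(stem.conv), stride=2)
    z = bn_train_ref(z, stem.bn.gamma.data, stem.bn.beta.data, stem.bn.eps)
    return max_pool_ref(relu_ref(z), 3, 2)


def channel_gate_ref(gate, x):
    pooled = x.mean(axis=(2, 3), keepdims=True)
    h = relu_ref(conv2d_ref(pooled, gate.squeeze.weight.data))
    return sigmoid_ref(conv2d_ref(h, gate.excite.weight.data))


def attention_ref(attn, z):
    sconv = conv2d_ref(z, attn.spatial_conv.weight.data,
                       _bias(attn.spatial_conv))
    sg = sigmoid_ref(bn_train_ref(sconv, attn.spatial_bn.gamma.data,
                                  attn.spatial_bn.beta.data, attn.spatial_bn.eps))
    cg = channel_gate_ref(attn.channel, z)
    return sg, cg, z * sg * cg


def conv_stack_ref(stack, x):
    x = relu_ref(bn_train_ref(
        conv2d_ref(x, stack.conv1.weight.data, _bias(stack.conv1)),
        stack.bn1.gamma.data, stack.bn1.beta.data, stack.bn1.eps))
    x = relu_ref(bn_train_ref(
        conv2d_ref(x, stack.conv2.weight.data, _bias(stack.conv2),
                   groups=stack.conv2.groups),
        stack.bn2.gamma.data, stack.bn2.beta.data, stack.bn2.eps))
    return bn_train_ref(
        conv2d_ref(x, stack.conv3.weight.data, _bias(stack.conv3)),
        stack.bn3.gamma.data, stack.bn3.beta.data, stack.bn3.eps)


def expert_block_ref(block, z):
    if block.cfg.use_scab:
        _, _, zf = attention_ref(block.attention, z)
    else:
        zf = z
    x3 = conv_stack_ref(block.stack, zf)
    if block.cfg.use_se:
        x3 = x3 * channel_gate_ref(block.se, x3)
    return relu_ref(x3 + z)


def transition_ref(tr, x):
    z = bn_train_ref(conv2d_ref(x, tr.conv.weight.data, _bias(tr.conv)),
                     tr.bn.gamma.data, tr.bn.beta.data, tr.bn.eps)
    return avg_pool_ref(relu_ref(z), 2)


def softmax_ref(scores):
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def routed_stage_ref(stage, x):
    pooled = x.mean(axis=(2, 3))
    weights = softmax_ref(pooled @ stage.router.w_r.data)
    outs = []
    for j, expert in enumerate(stage.experts):
        outs.append(expert_block_ref(expert, x) * weights[:, j, None, None, None])
    return np.concatenate(outs, axis=1), weights
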