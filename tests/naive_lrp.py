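"""Independent per-neuron relevance propagation, written with explicit loops.

This is the test oracle for the vectorised rules in gaitscope.relprop: every
redistribution is computed neuron by neuron (double loops over inputs and
outputs, quadruple loops for convolutions) directly from the rule
definitions. It shares no code with the implementation under test beyond the
ModelGraph forward pass that supplies activations.
"""

from __future__ import annotations

import numpy as np

from gaitscope.model import Conv1D, Dense, Flatten, MaxPool1D, ModelGraph, ReLU

TINY = 1e-12


def _sign(z: float) -> float:
    return 1.0 if z >= 0 else -1.0


def naive_dense_epsilon(a, w, b, r_out, eps):
    J, K = w.shape
    r_in = np.zeros(J)
    for k in range(K):
        z = b[k]
        for j in range(J):
            z += a[j] * w[j, k]
        denom = z + eps * _sign(z)
        if abs(denom) < TINY:
            denom = _sign(denom) * TINY
        for j in range(J):
            r_in[j] += a[j] * w[j, k] / denom * r_out[k]
    return r_in


def naive_dense_alphabeta(a, w, b, r_out, alpha, beta):
    J, K = w.shape
    r_in = np.zeros(J)
    for k in range(K):
        zp = max(b[k], 0.0)
        zn = min(b[k], 0.0)
        for j in range(J):
            c = a[j] * w[j, k]
            zp += max(c, 0.0)
            zn += min(c, 0.0)
        if zp == 0.0:
            # no positive contribution at all: signed proportional fallback
            denom = zn if abs(zn) >= TINY else -TINY
            for j in range(J):
                r_in[j] += a[j] * w[j, k] / denom * r_out[k]
            continue
        if abs(zp) < TINY:
            zp = TINY
        if abs(zn) < TINY:
            zn = -TINY
        for j in range(J):
            c = a[j] * w[j, k]
            r_in[j] += (alpha * max(c, 0.0) / zp
                        - beta * min(c, 0.0) / zn) * r_out[k]
    return r_in


def naive_conv_alphabeta(a, w, b, r_out, alpha, beta):
    O, C, K = w.shape
    _, L = a.shape
    Lo = r_out.shape[1]
    r_in = np.zeros_like(a)
    for o in range(O):
        for l in range(Lo):
            zp = max(b[o], 0.0)
            zn = min(b[o], 0.0)
            for c in range(C):
                for kk in range(K):
                    v = a[c, l + kk] * w[o, c, kk]
                    zp += max(v, 0.0)
                    zn += min(v, 0.0)
            if zp == 0.0:
                denom = zn if abs(zn) >= TINY else -TINY
                for c in range(C):
                    for kk in range(K):
                        r_in[c, l + kk] += (a[c, l + kk] * w[o, c, kk]
                                            / denom * r_out[o, l])
                continue
            if abs(zp) < TINY:
                zp = TINY
            if abs(zn) < TINY:
                zn = -TINY
            for c in range(C):
                for kk in range(K):
                    v = a[c, l + kk] * w[o, c, kk]
                    r_in[c, l + kk] += (alpha * max(v, 0.0) / zp
                                        - beta * min(v, 0.0) / zn) * r_out[o, l]
    return r_in


def naive_conv_epsilon(a, w, b, r_out, eps):
    O, C, K = w.shape
    Lo = r_out.shape[1]
    r_in = np.zeros_like(a)
    for o in range(O):
        for l in range(Lo):
            z = b[o]
            for c in range(C):
                for kk in range(K):
                    z += a[c, l + kk] * w[o, c, kk]
            denom = z + eps * _sign(z)
            if abs(denom) < TINY:
                denom = _sign(denom) * TINY
            for c in range(C):
                for kk in range(K):
                    r_in[c, l + kk] += (a[c, l + kk] * w[o, c, kk] / denom
                                        * r_out[o, l])
    return r_in


def naive_maxpool(a, size, r_out):
    C, L = a.shape
    Lo = L // size
    r_in = np.zeros_like(a)
    for c in range(C):
        for l in range(Lo):
            window = a[c, l * size:(l + 1) * size]
            r_in[c, l * size + int(np.argmax(window))] = r_out[c, l]
    return r_in


def naive_lrp(model: ModelGraph, x: np.ndarray, rule_map: dict,
              alpha: float = 1.0, beta: float = 0.0,
              eps: float = 0.01, target: int | None = None) -> np.ndarray:
    """Full backward pass with the naive per-neuron rules."""
    acts = model.forward_with_cache(np.asarray(x, dtype=float)[None])
    logits = acts[-1][0]
    t = int(np.argmax(logits)) if target is None else target
    r = np.zeros_like(logits)
    r[t] = logits[t]
    for i in range(len(model.layers) - 2, -1, -1):
        layer = model.layers[i]
        a = acts[i][0]
        if isinstance(layer, Dense):
            b = layer.b if layer.use_bias else np.zeros(layer.w.shape[1])
            if rule_map.get("dense", "epsilon") == "epsilon":
                r = naive_dense_epsilon(a, layer.w, b, r, eps)
            else:
                r = naive_dense_alphabeta(a, layer.w, b, r, alpha, beta)
        elif isinstance(layer, Conv1D):
            b = layer.b if layer.use_bias else np.zeros(layer.w.shape[0])
            if rule_map.get("conv1d", "alphabeta") == "alphabeta":
                r = naive_conv_alphabeta(a, layer.w, b, r, alpha, beta)
            else:
                r = naive_conv_epsilon(a, layer.w, b, r, eps)
        elif isinstance(layer, ReLU):
            pass
        elif isinstance(layer, MaxPool1D):
            r = naive_maxpool(a, layer.size, r)
        elif isinstance(layer, Flatten):
            r = r.reshape(a.shape)
    return r
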