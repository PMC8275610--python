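"""Layer-wise relevance propagation (LRP) through the epoch classifier.

LRP decomposes a network output f(x) — here the pre-softmax logit of a chosen
class — into per-input relevance values R_i by walking the layer graph
backwards under a conservation constraint: the relevance leaving a layer
equals the relevance entering it, up to explicitly logged absorption by biases
and stabilisers.

Rules implemented (for ReLU networks, i.e. positive monotone activations):

* **alpha-beta rule** (convolutional layers; defaults alpha=1, beta=0, with
  alpha - beta = 1 and beta >= 0): positive and negative contributions
  a_j * w_jk are redistributed separately in proportion to their share of the
  positive / negative pre-activation. With alpha1beta0 only excitatory
  contributions propagate, which yields crisp heatmaps of the signal
  morphology driving a class.
* **epsilon rule** (dense layers; default epsilon = 0.01): contributions are
  normalised by the pre-activation plus a signed stabiliser
  epsilon * sign(z) (sign(0) = +1), which absorbs relevance where
  contributions are weak or contradictory.
* ReLU passes relevance through unchanged; max-pooling routes it
  winner-take-all to the argmax; flatten is an index-preserving reshape.

Bias relevance is absorbed, never redistributed to inputs; each layer's
relevance sum is recorded in an audit trail so conservation can be checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .model import (Conv1D, Dense, Flatten, MaxPool1D, ModelGraph, ReLU,
                    Softmax)

__all__ = [
    "LrpConfig", "RelevanceMap",
    "lrp_decompose", "channel_relevance", "render_heatmap",
    "dense_epsilon_rule", "dense_alphabeta_rule", "conv_alphabeta_rule",
]

_TINY = 1e-12


@dataclass(frozen=True)
class LrpConfig:
    """Rule parameters; alpha - beta = 1 and beta >= 0 are enforced."""

    alpha: float = 1.0
    beta: float = 0.0
    epsilon: float = 0.01
    rule_map: dict = field(default_factory=lambda: {"conv1d": "alphabeta",
                                                    "dense": "epsilon"})
    target: str | int | None = None   # None -> explain the predicted class

    def __post_init__(self) -> None:
        if abs(self.alpha - self.beta - 1.0) > 1e-12:
            raise ValueError("alpha - beta must equal 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        for kind, rule in self.rule_map.items():
            if rule not in ("alphabeta", "epsilon"):
                raise ValueError(f"unknown rule {rule!r} for {kind}")


@dataclass
class RelevanceMap:
    """Input relevance aligned to an epoch, plus the conservation audit."""

    R: np.ndarray                  # (4, 128)
    explained_logit: float
    target_label: str
    audit: list[dict]              # one entry per traversed layer

    def conservation_error(self) -> float:
        """Relative difference between input relevance sum and the logit."""
        denom = max(abs(self.explained_logit), _TINY)
        return abs(self.R.sum() - self.explained_logit) / denom


def _signed(z: np.ndarray) -> np.ndarray:
    """sign with sign(0) = +1."""
    return np.where(z >= 0, 1.0, -1.0)


def dense_epsilon_rule(a: np.ndarray, w: np.ndarray, b: np.ndarray,
                       r_out: np.ndarray, epsilon: float) -> np.ndarray:
    """Epsilon rule on an affine layer: R_j = sum_k a_j w_jk / (z_k + eps*sign(z_k)) R_k.

    ``a``: input activations (J,); ``w``: (J, K); ``b``: (K,). The stabiliser
    takes the sign of the denominator; its share of relevance (and the bias
    share) is absorbed.
    """
    z = a @ w + b
    denom = z + epsilon * _signed(z)
    denom = np.where(np.abs(denom) < _TINY, _signed(denom) * _TINY, denom)
    s = r_out / denom
    return a * (w @ s)


def dense_alphabeta_rule(a: np.ndarray, w: np.ndarray, b: np.ndarray,
                         r_out: np.ndarray, alpha: float,
                         beta: float) -> np.ndarray:
    """Alpha-beta rule on an affine layer.

    Positive and negative parts of the contributions a_j w_jk are
    redistributed separately; the bias enters each denominator (its share is
    absorbed, not propagated). Degenerate outputs with no positive
    contribution at all (z+ = 0, only possible for unrectified neurons such
    as the logits) fall back to signed proportional shares — the epsilon-rule
    limit eps -> 0 — which keeps relevance conserved.
    """
    contrib = a[:, None] * w                       # (J, K)
    pos = np.clip(contrib, 0.0, None)
    neg = np.clip(contrib, None, 0.0)
    zp = pos.sum(axis=0) + np.clip(b, 0.0, None)
    zn = neg.sum(axis=0) + np.clip(b, None, 0.0)
    degenerate = zp == 0.0
    zp = np.where(np.abs(zp) < _TINY, _TINY, zp)
    zn = np.where(np.abs(zn) < _TINY, -_TINY, zn)
    r_ab = np.where(degenerate, 0.0, r_out)
    r_in = alpha * pos @ (r_ab / zp) - beta * neg @ (r_ab / zn)
    if degenerate.any():
        # z+ = 0 implies b+ = 0, so the full pre-activation equals z-
        r_in = r_in + contrib @ (np.where(degenerate, r_out, 0.0) / zn)
    return r_in


def conv_alphabeta_rule(a: np.ndarray, w: np.ndarray, b: np.ndarray,
                        r_out: np.ndarray, alpha: float,
                        beta: float) -> np.ndarray:
    """Alpha-beta rule applied per output position over its receptive field.

    ``a``: (C, L); ``w``: (O, C, K); ``b``: (O,); ``r_out``: (O, Lo) with
    Lo = L - K + 1 (stride 1, valid convolution). Outputs with z+ = 0 use
    the same signed-proportional fallback as the dense rule.
    """
    k = w.shape[2]
    win = sliding_window_view(a, k, axis=1)            # (C, Lo, K)
    contrib = win[None] * w[:, :, None, :]             # (O, C, Lo, K)
    pos = np.clip(contrib, 0.0, None)
    neg = np.clip(contrib, None, 0.0)
    zp = pos.sum(axis=(1, 3)) + np.clip(b, 0.0, None)[:, None]   # (O, Lo)
    zn = neg.sum(axis=(1, 3)) + np.clip(b, None, 0.0)[:, None]
    degenerate = zp == 0.0
    zp = np.where(np.abs(zp) < _TINY, _TINY, zp)
    zn = np.where(np.abs(zn) < _TINY, -_TINY, zn)
    r_ab = np.where(degenerate, 0.0, r_out)
    msg = (alpha * pos * (r_ab / zp)[:, None, :, None]
           - beta * neg * (r_ab / zn)[:, None, :, None])
    if degenerate.any():
        # no positive contribution anywhere: signed proportional fallback
        r_deg = np.where(degenerate, r_out, 0.0)
        msg = msg + contrib * (r_deg / zn)[:, None, :, None]
    msg = msg.sum(axis=0)                              # (C, Lo, K)
    r_in = np.zeros_like(a)
    lo = r_out.shape[1]
    for j in range(k):
        r_in[:, j:j + lo] += msg[:, :, j]
    return r_in


def lrp_decompose(model: ModelGraph, epoch, cfg: LrpConfig = LrpConfig()
                  ) -> RelevanceMap:
    """Decompose one epoch's logit into a 4 x 128 input relevance map.

    Relevance is initialised at the pre-softmax logit of the target class
    (default: the predicted class) and propagated backwards using the rule
    configured per layer kind.
    """
    x = epoch.x if hasattr(epoch, "x") else np.asarray(epoch, dtype=float)
    acts = model.forward_with_cache(x[None])
    logits = acts[-1][0]

    if cfg.target is None:
        target_idx = int(np.argmax(logits))
    elif isinstance(cfg.target, str):
        target_idx = model.label_space.index(cfg.target)
    else:
        target_idx = int(cfg.target)
    logit = float(logits[target_idx])

    r = np.zeros_like(logits)
    r[target_idx] = logit
    audit = [{"layer": "output", "kind": "logit", "relevance_sum": logit}]

    for i in range(len(model.layers) - 2, -1, -1):   # skip terminal softmax
        layer = model.layers[i]
        a = acts[i][0]
        if isinstance(layer, Dense):
            rule = cfg.rule_map.get("dense", "epsilon")
            b = layer.b if layer.use_bias else np.zeros(layer.w.shape[1])
            if rule == "epsilon":
                r = dense_epsilon_rule(a, layer.w, b, r, cfg.epsilon)
            else:
                r = dense_alphabeta_rule(a, layer.w, b, r, cfg.alpha, cfg.beta)
        elif isinstance(layer, Conv1D):
            rule = cfg.rule_map.get("conv1d", "alphabeta")
            b = layer.b if layer.use_bias else np.zeros(layer.w.shape[0])
            if rule == "alphabeta":
                r = conv_alphabeta_rule(a, layer.w, b, r, cfg.alpha, cfg.beta)
            else:  # epsilon on a conv layer, via its unrolled affine form
                r = _conv_epsilon(a, layer.w, b, r, cfg.epsilon)
        elif isinstance(layer, ReLU):
            pass  # component-wise positive monotone: relevance unchanged
        elif isinstance(layer, MaxPool1D):
            r = _maxpool_redistribute(layer, a, r)
        elif isinstance(layer, Flatten):
            r = r.reshape(a.shape)
        elif isinstance(layer, Softmax):  # pragma: no cover - excluded above
            continue
        else:
            raise ValueError(f"no relevance rule for layer kind {layer.kind!r}")
        audit.append({"layer": i, "kind": layer.kind,
                      "relevance_sum": float(r.sum())})

    return RelevanceMap(R=r, explained_logit=logit,
                        target_label=model.label_space[target_idx],
                        audit=audit)


def _conv_epsilon(a, w, b, r_out, epsilon):
    k = w.shape[2]
    win = sliding_window_view(a, k, axis=1)
    z = np.einsum("clk,ock->ol", win, w) + b[:, None]
    denom = z + epsilon * _signed(z)
    denom = np.where(np.abs(denom) < _TINY, _signed(denom) * _TINY, denom)
    s = r_out / denom
    msg = (win[None] * w[:, :, None, :] * s[:, None, :, None]).sum(axis=0)
    r_in = np.zeros_like(a)
    lo = r_out.shape[1]
    for j in range(k):
        r_in[:, j:j + lo] += msg[:, :, j]
    return r_in


def _maxpool_redistribute(layer: MaxPool1D, a: np.ndarray,
                          r_out: np.ndarray) -> np.ndarray:
    """Winner-take-all: all relevance of a pooled output goes to its argmax."""
    size = layer.size
    c, n = a.shape
    lo = n // size
    ar = a[:, :lo * size].reshape(c, lo, size)
    amax = ar.argmax(axis=2)
    r_in = np.zeros_like(a)
    ci, li = np.meshgrid(np.arange(c), np.arange(lo), indexing="ij")
    flat_pos = li * size + amax
    r_in[ci, flat_pos] = r_out
    return r_in


def channel_relevance(rmap: RelevanceMap) -> np.ndarray:
    """Per-channel relevance totals (a_x, a_y, a_z, ||a||); they partition
    the total input relevance exactly."""
    return rmap.R.sum(axis=1)


def render_heatmap(epoch, rmap: RelevanceMap, out, fs_hz: float = 50.0):
    """Overlay relevance on the four signal traces and write a figure.

    Positive relevance (supporting the explained class, conventionally
    "toward MS") is drawn in hot hues, negative relevance in cold hues, and
    near-zero relevance in black; the colour scale is symmetric about zero.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap, Normalize

    x = epoch.x if hasattr(epoch, "x") else np.asarray(epoch, dtype=float)
    cmap = LinearSegmentedColormap.from_list(
        "relevance", ["#0033ff", "#000000", "#ff2200"])
    vmax = float(np.max(np.abs(rmap.R)))
    norm = Normalize(vmin=-vmax if vmax else -1.0, vmax=vmax if vmax else 1.0)
    t = np.arange(x.shape[1]) / fs_hz
    names = ("$a_x$", "$a_y$", "$a_z$", r"$\|a\|$")
    fig, axes = plt.subplots(4, 1, figsize=(8, 7), sharex=True)
    for i, ax in enumerate(axes):
        ax.plot(t, x[i], color="0.75", lw=0.8, zorder=1)
        ax.scatter(t, x[i], c=rmap.R[i], cmap=cmap, norm=norm, s=8, zorder=2)
        ax.set_ylabel(names[i])
    axes[-1].set_xlabel("time [s]")
    fig.suptitle(f"relevance toward {rmap.target_label!r} "
                 f"(logit {rmap.explained_logit:.3f})")
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=norm)
    fig.colorbar(sm, ax=axes, label="$R_i$")
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
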