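"""Class-representative gait epochs via DTW Barycenter Averaging (DBA).

A representative epoch of a class is the DTW barycenter of a selection of
high-confidence, correctly classified epochs of that class: dynamic time
warping aligns epochs despite cadence differences, and DBA iteratively
averages the aligned samples into a single 4 x 128 template. The template is
then re-scored by the trained classifier and explained with relevance
propagation, giving a macro-level picture of what each class's gait looks
like to the model.

Conventions: classic dynamic-programming DTW with squared-difference local
cost, unit step pattern {(1,0), (0,1), (1,1)}, no band constraint, diagonal
preferred on ties. Multichannel epochs are averaged under a *shared* warping
computed on the magnitude channel, which keeps the four channels temporally
aligned; the DBA objective (sum of squared-cost DTW distances on the
magnitude channel) is non-increasing over iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelGraph, predict_epoch
from .relprop import LrpConfig, RelevanceMap, lrp_decompose

__all__ = [
    "DbaSelection", "RepresentativeEpoch",
    "dtw_distance", "select_epochs", "dba_average", "score_representative",
]

MAG_CHANNEL = 3

try:  # optional JIT: the DP recurrence dominates DBA runtime
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not a or not callable(a[0]) else a[0]


@_njit(cache=True)
def _dtw_accumulate(local: np.ndarray) -> np.ndarray:
    n, m = local.shape
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = local[i - 1, j - 1] + best
    return acc


@dataclass(frozen=True)
class DbaSelection:
    """Which epochs feed the barycenter of a class.

    Defaults follow the reference procedure: up to 2000 correctly classified
    epochs with posterior > 0.85 for the class, and at most 40 epochs (< 50 %
    of one test's windows) contributed by any single test.
    """

    n_epochs: int = 2000
    probability_threshold: float = 0.85
    max_per_test: int = 40
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.probability_threshold < 1.0:
            raise ValueError("probability threshold must lie in (0, 1)")
        if self.max_per_test < 1:
            raise ValueError("per-test cap must be >= 1")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


@dataclass
class RepresentativeEpoch:
    """DBA barycenter of one class plus its model posterior and relevance."""

    barycenter: np.ndarray           # (4, 128)
    label: str
    posterior: float | None = None
    probabilities: np.ndarray | None = None
    relevance: RelevanceMap | None = None
    objective_trace: list[float] = field(default_factory=list)
    n_epochs: int = 0


# ---------------------------------------------------------------------------
# DTW


def dtw_distance(x: np.ndarray, y: np.ndarray, cost: str = "squared",
                 ) -> tuple[float, list[tuple[int, int]]]:
    """Dynamic-programming DTW between two 1-D sequences.

    Returns the accumulated cost and one optimal path (list of index pairs,
    (0,0) ... (n-1,m-1)). Local cost is the squared difference by default
    (``cost="abs"`` for absolute difference); steps are {(1,0),(0,1),(1,1)}
    with the diagonal preferred on ties; no band constraint.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("DTW of empty sequence")
    n, m = x.size, y.size
    d = (x[:, None] - y[None, :])
    local = d * d if cost == "squared" else np.abs(d)
    acc = _dtw_accumulate(local)

    # traceback, diagonal preferred on ties
    path = [(n - 1, m - 1)]
    i, j = n, m
    while (i, j) != (1, 1):
        options = [(acc[i - 1, j - 1], (i - 1, j - 1)),
                   (acc[i - 1, j], (i - 1, j)),
                   (acc[i, j - 1], (i, j - 1))]
        best = min(o[0] for o in options)
        for val, (pi, pj) in options:       # first option listed is diagonal
            if val == best:
                i, j = pi, pj
                break
        path.append((i - 1, j - 1))
    path.reverse()
    return float(acc[n, m]), path


# ---------------------------------------------------------------------------
# epoch selection


def select_epochs(predictions: pd.DataFrame, selection: DbaSelection,
                  rng: np.random.Generator | int | None = None,
                  ) -> dict[str, np.ndarray]:
    """Pick the epochs that feed each class barycenter.

    ``predictions`` needs columns: ``label`` (true), ``pred`` (predicted),
    ``prob`` (posterior of the true class), ``test_id``, ``index`` (row into
    the epoch array). Per class: keep correct predictions with
    prob > threshold, cap contributions per test, then sample up to
    ``n_epochs`` uniformly without replacement (all of them, with a warning,
    if fewer qualify).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out: dict[str, np.ndarray] = {}
    for cls, grp in predictions.groupby("label", sort=True):
        ok = grp[(grp["pred"] == grp["label"])
                 & (grp["prob"] > selection.probability_threshold)]
        if ok.empty:
            raise ValueError(f"no qualifying epochs for class {cls!r}")
        capped = []
        for _, tgrp in ok.groupby("test_id", sort=True):
            idx = tgrp["index"].to_numpy()
            if idx.size > selection.max_per_test:
                idx = rng.choice(idx, size=selection.max_per_test, replace=False)
            capped.append(idx)
        pool = np.concatenate(capped)
        if pool.size > selection.n_epochs:
            pool = rng.choice(pool, size=selection.n_epochs, replace=False)
        else:
            warnings.warn(f"class {cls!r}: only {pool.size} qualifying epochs "
                          f"(target {selection.n_epochs}); using all")
        out[str(cls)] = np.sort(pool)
    return out


# ---------------------------------------------------------------------------
# DBA


def _dba_objective(bary: np.ndarray, seqs: np.ndarray) -> float:
    """Sum of squared-cost DTW distances on the magnitude channel."""
    return float(sum(dtw_distance(bary[MAG_CHANNEL], s[MAG_CHANNEL])[0]
                     for s in seqs))


def dba_average(epochs: np.ndarray, max_iter: int = 30, tol: float = 1e-6,
                label: str = "") -> RepresentativeEpoch:
    """DTW Barycenter Averaging of a stack of (4, T) epochs.

    Initialises at the medoid (minimum summed DTW distance on the magnitude
    channel) and iterates the DBA update — align every sequence to the
    current barycenter, then average the samples assigned to each barycenter
    index — until the objective improves by less than ``tol`` or ``max_iter``
    is reached. All four channels are warped and averaged under the shared
    magnitude-channel alignment.
    """
    seqs = np.asarray(epochs, dtype=float)
    if seqs.ndim == 2:
        seqs = seqs[None]
    if seqs.shape[0] == 0:
        raise ValueError("DBA of empty epoch set")
    k, c, t = seqs.shape

    if k == 1:
        return RepresentativeEpoch(barycenter=seqs[0].copy(), label=label,
                                   objective_trace=[0.0], n_epochs=1)

    # medoid initialisation on the magnitude channel
    mags = seqs[:, MAG_CHANNEL]
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            dij, _ = dtw_distance(mags[i], mags[j])
            dist[i, j] = dist[j, i] = dij
    bary = seqs[int(np.argmin(dist.sum(axis=1)))].copy()

    trace = [_dba_objective(bary, seqs)]
    for _ in range(max_iter):
        sums = np.zeros((c, t))
        counts = np.zeros(t)
        for s in seqs:
            _, path = dtw_distance(bary[MAG_CHANNEL], s[MAG_CHANNEL])
            for bi, si in path:
                sums[:, bi] += s[:, si]
                counts[bi] += 1
        new_bary = sums / counts[None, :]     # every index lies on some path
        obj = _dba_objective(new_bary, seqs)
        if obj > trace[-1] + 1e-12:
            break                              # defensive; DBA is non-increasing
        bary = new_bary
        trace.append(obj)
        if trace[-2] - trace[-1] < tol:
            break
    return RepresentativeEpoch(barycenter=bary, label=label,
                               objective_trace=trace, n_epochs=k)


def score_representative(model: ModelGraph, rep: RepresentativeEpoch,
                         lrp_cfg: LrpConfig | None = None) -> RepresentativeEpoch:
    """Attach the model posterior for the class and a relevance map."""
    if rep.barycenter.shape[0] != 4:
        raise ValueError("barycenter must have 4 channels")
    pred = predict_epoch(model, rep.barycenter)
    if rep.label in model.label_space:
        rep.posterior = float(
            pred.probabilities[model.label_space.index(rep.label)])
    else:
        rep.posterior = float(pred.probabilities.max())
    rep.probabilities = pred.probabilities
    cfg = lrp_cfg if lrp_cfg is not None else LrpConfig(
        target=rep.label if rep.label in model.label_space else None)
    rep.relevance = lrp_decompose(model, rep.barycenter, cfg)
    return rep
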