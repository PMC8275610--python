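"""Hand-rolled fixtures shared by several test modules."""

from __future__ import annotations

import numpy as np

from gaitscope import preprocessing as pp


def make_separable_dataset(n_per_class: int = 60, seed: int = 0,
                           classes=("A", "B"), n_subjects: int = 4
                           ) -> pp.EpochDataset:
    """Trivially separable epochs: class-specific tones plus light noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(128) / 50.0
    X, labels, sids, tids, starts = [], [], [], [], []
    for ci, cls in enumerate(classes):
        freq = 1.5 + 2.0 * ci
        for i in range(n_per_class):
            x = np.stack([np.sin(2 * np.pi * freq * t + ph)
                          for ph in (0, 0.5, 1.0, 1.5)])
            x = x + rng.normal(0, 0.1, size=x.shape)
            X.append(x)
            labels.append(cls)
            sids.append(f"{cls}_subj{i % n_subjects}")
            tids.append(f"{cls}_subj{i % n_subjects}_test{i // n_subjects}")
            starts.append(0)
    return pp.EpochDataset(np.stack(X), np.array(labels), np.array(sids),
                           np.array(tids), np.array(starts), tuple(classes))
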