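"""Greedy maximum-distance (farthest-point) batch selection.

Iteratively picks the pool point whose minimum Euclidean distance to the
already-selected set is largest — the classic max-min acquisition for
assembling structurally diverse training batches.  The feature map is
arbitrary: global descriptors by default, but any per-structure vector
(e.g. model gradient features) can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FeaturePool:
    """N_pool x F feature matrix with per-row identifiers."""

    features: np.ndarray
    identifiers: list = field(default_factory=list)

    def __post_init__(self):
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if self.features.shape[0] < 1:
            raise ValueError("feature pool must contain at least one row")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        if not self.identifiers:
            self.identifiers = list(range(self.features.shape[0]))


def farthest_point_selection(
    pool: FeaturePool, batch_size: int, already_selected=()
) -> list[int]:
    """Return ``batch_size`` pool indices in greedy max-min order.

    Each pick maximizes the minimum distance to the union of previous picks
    and ``already_selected``; ties break toward the lowest index.  With
    nothing pre-selected, the seed pick is the point farthest from the pool
    mean (deterministic and scale-free).
    """
    X = pool.features
    n = X.shape[0]
    already = sorted(set(int(i) for i in already_selected))
    if any(i < 0 or i >= n for i in already):
        raise IndexError("already_selected index out of range")
    if batch_size < 0 or batch_size > n - len(already):
        raise ValueError(
            f"batch_size {batch_size} exceeds remaining pool ({n - len(already)})"
        )
    remaining = np.ones(n, dtype=bool)
    remaining[already] = False
    if already:
        mind = np.min(
            np.linalg.norm(X[:, None, :] - X[None, already, :], axis=-1), axis=1
        )
    else:
        mind = np.full(n, np.inf)
    picks = []
    for _ in range(batch_size):
        if np.isinf(mind[remaining]).all():
            # nothing selected anywhere yet: seed with the point farthest
            # from the pool mean
            dist_to_mean = np.linalg.norm(X - X.mean(axis=0), axis=1)
            cand = np.where(remaining)[0]
            pick = int(cand[np.argmax(dist_to_mean[cand])])
        else:
            cand = np.where(remaining)[0]
            pick = int(cand[np.argmax(mind[cand])])
        picks.append(pick)
        remaining[pick] = False
        d = np.linalg.norm(X - X[pick], axis=1)
        mind = np.minimum(mind, d)
    return picks
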