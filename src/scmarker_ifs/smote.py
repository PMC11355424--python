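"""Synthetic minority oversampling (SMOTE), implemented from first principles.

Every minority class is oversampled up to the majority class size by
interpolating between a random class member x and one of its k nearest
same-class neighbours x': s = x + λ(x' − x), λ ~ Uniform(0, 1). Original
rows are preserved verbatim and come first; neighbours are searched within
the class only, so no label information leaks across classes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .dataset import ValidationError

log = logging.getLogger(__name__)


@dataclass
class SmoteParams:
    """k_neighbors: neighbours considered per base sample (reduced to n−1
    for classes with fewer members); balancing target is the majority size."""

    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValidationError("k_neighbors must be >= 1")


class SyntheticProvenance(NamedTuple):
    """Where one synthetic row came from: global indices into the input X."""

    klass: object
    base_index: int
    neighbor_index: int
    lam: float


class SmoteResult(NamedTuple):
    X: np.ndarray
    y: list
    provenance: list


def smote_balance(X, y, params: SmoteParams | None = None) -> SmoteResult:
    """Balance all class counts up to the majority class size.

    Returns the augmented matrix (originals first, synthetics appended in
    class order), the augmented labels, and one provenance record per
    synthetic row naming its generating pair and interpolation weight.
    Deterministic given ``params.seed``.
    """
    params = params or SmoteParams()
    X = np.asarray(X, dtype=np.float64)
    y = list(y)
    if X.ndim != 2 or len(y) != X.shape[0] or X.shape[0] == 0:
        raise ValidationError("X must be a non-empty matrix aligned with y")
    counts = Counter(y)
    if len(counts) < 2:
        raise ValidationError("SMOTE requires >= 2 classes")
    majority = max(counts.values())
    classes = list(dict.fromkeys(y))

    rng = np.random.default_rng(params.seed)
    new_rows, new_labels, provenance = [], [], []
    for klass in classes:
        need = majority - counts[klass]
        if need == 0:
            continue
        idx = np.flatnonzero(np.array([lab == klass for lab in y]))
        n_c = len(idx)
        if n_c == 1:
            log.warning("class %r has a single sample; replicating it verbatim "
                        "%d times (interpolation impossible)", klass, need)
            for _ in range(need):
                new_rows.append(X[idx[0]].copy())
                new_labels.append(klass)
                provenance.append(SyntheticProvenance(klass, int(idx[0]), int(idx[0]), 0.0))
            continue
        k = min(params.k_neighbors, n_c - 1)
        if k < params.k_neighbors:
            log.warning("class %r has %d samples; k_neighbors reduced to %d",
                        klass, n_c, k)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X[idx])
        # neighbour 0 is the point itself
        neighbor_ids = nn.kneighbors(X[idx], return_distance=False)[:, 1:]
        for _ in range(need):
            b = int(rng.integers(n_c))
            nb = int(neighbor_ids[b, rng.integers(k)])
            lam = float(rng.random())
            x, xp = X[idx[b]], X[idx[nb]]
            new_rows.append(x + lam * (xp - x))
            new_labels.append(klass)
            provenance.append(SyntheticProvenance(klass, int(idx[b]), int(idx[nb]), lam))

    if not new_rows:
        return SmoteResult(X=X, y=y, provenance=[])
    X_out = np.vstack([X, np.array(new_rows)])
    return SmoteResult(X=X_out, y=y + new_labels, provenance=provenance)
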