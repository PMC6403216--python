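"""From-scratch SMOTE oversampling of the minority class.

Synthetic samples are drawn on the concatenated (x1 || x2) feature vector
so the two chromosome signals of one synthetic sample stay coherent: each
new point is p + u*(q - p) with u ~ Uniform(0, 1), p a minority sample and
q one of p's k nearest minority neighbors under Euclidean distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .vectorize import FeatureVector, SampleFeatures

__all__ = ["SmoteConfig", "smote_oversample", "balance_classes"]

logger = logging.getLogger(__name__)


@dataclass
class SmoteConfig:
    target_count: int
    k_neighbors: int = 5
    seed: int = 0
    reduce_k: bool = True  # shrink k to n-1 when the minority is tiny


def smote_oversample(
    minority: Sequence[SampleFeatures], config: SmoteConfig
) -> List[SampleFeatures]:
    """Return exactly ``target_count - len(minority)`` synthetic samples.

    Minority points are visited round-robin until the deficit is filled.
    Deterministic under ``config.seed``; synthetic samples carry the
    minority label and generated ids.
    """
    n = len(minority)
    if n < 2:
        raise ValueError(f"cannot interpolate a minority of size {n} (< 2)")
    if config.target_count < n:
        raise ValueError(
            f"target_count {config.target_count} is below minority size {n}")
    k = config.k_neighbors
    if k < 1:
        raise ValueError(f"k_neighbors must be >= 1, got {k}")
    if k >= n:
        if not config.reduce_k:
            raise ValueError(f"k_neighbors={k} must be < minority size {n}")
        logger.warning("reducing k_neighbors from %d to %d (minority size %d)",
                       k, n - 1, n)
        k = n - 1

    deficit = config.target_count - n
    if deficit == 0:
        return []

    X = np.stack([s.concatenated for s in minority])
    dist = cdist(X, X)
    np.fill_diagonal(dist, np.inf)
    # stable k-NN table: each row holds the indices of the k nearest others
    neighbors = np.argsort(dist, axis=1, kind="stable")[:, :k]

    rng = np.random.default_rng(config.seed)
    len1 = minority[0].x1.target_len
    label = minority[0].label
    synthetic: List[SampleFeatures] = []
    for j in range(deficit):
        i = j % n
        q = neighbors[i, rng.integers(k)]
        u = rng.uniform()
        new = X[i] + u * (X[q] - X[i])
        synthetic.append(SampleFeatures(
            sample_id=f"{minority[i].sample_id}_smote{j + 1}",
            x1=FeatureVector("1", new[:len1], len1),
            x2=FeatureVector("19", new[len1:], len(new) - len1),
            label=label,
        ))
    return synthetic


def balance_classes(
    samples: Sequence[SampleFeatures],
    k_neighbors: int = 5,
    seed: int = 0,
) -> List[SampleFeatures]:
    """Up-sample the minority class to match the majority count.

    Returns originals plus synthetic minority samples; a no-op when the
    classes are already balanced.
    """
    by_label: dict = {}
    for s in samples:
        if s.label is None:
            raise ValueError(f"sample {s.sample_id} has no label")
        by_label.setdefault(s.label, []).append(s)
    if len(by_label) != 2:
        raise ValueError(
            f"expected exactly two classes, got {sorted(by_label)}")
    (lab_a, grp_a), (lab_b, grp_b) = sorted(
        by_label.items(), key=lambda kv: len(kv[1]))
    if len(grp_a) == len(grp_b):
        return list(samples)
    logger.info("up-sampling minority class %r from %d to %d",
                lab_a, len(grp_a), len(grp_b))
    config = SmoteConfig(target_count=len(grp_b), k_neighbors=k_neighbors,
                         seed=seed)
    return list(samples) + smote_oversample(grp_a, config)
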