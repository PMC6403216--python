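"""Chromosome signal extraction and fixed-length vectorization.

A chromosome's bins, taken in relative order, yield an ordered log2 signal;
genomic start/length information is intentionally discarded.  Signals are
harmonized to canonical lengths (1869 for chr1, 649 for chr19) by contiguous
group averaging (dense array platforms) or, for shorter-than-target inputs,
by linear interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .profile_io import CnProfile, VALID_LABELS, normalize_chrom

__all__ = [
    "CHR1_TARGET_LEN",
    "CHR19_TARGET_LEN",
    "FeatureVector",
    "SampleFeatures",
    "EmptyChromosomeError",
    "extract_chrom_signal",
    "group_partition",
    "reformat_signal",
    "featurize",
    "write_features",
    "read_features",
]

logger = logging.getLogger(__name__)

# Canonical fixed vector lengths for chr1 and chr19.
CHR1_TARGET_LEN = 1869
CHR19_TARGET_LEN = 649


class EmptyChromosomeError(ValueError):
    """Requested chromosome has no bins in the profile."""


@dataclass
class FeatureVector:
    """Fixed-length ordered log2 signal for one chromosome."""

    chrom: str
    values: np.ndarray
    target_len: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != self.target_len:
            raise ValueError(
                f"chr{self.chrom} feature vector must have length "
                f"{self.target_len}, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"chr{self.chrom} feature vector has non-finite values")


@dataclass
class SampleFeatures:
    """Per-sample chr1/chr19 feature vectors with an optional class label."""

    sample_id: str
    x1: FeatureVector
    x2: FeatureVector
    label: Optional[str] = None

    def __post_init__(self):
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValueError(
                f"label must be one of {VALID_LABELS} or None, got {self.label!r}")

    @property
    def concatenated(self) -> np.ndarray:
        """x1 followed by x2, the joint feature space used for oversampling."""
        return np.concatenate([self.x1.values, self.x2.values])


def extract_chrom_signal(profile: CnProfile, chrom: str) -> np.ndarray:
    """Log2 values of a chromosome's bins in relative (positional) order."""
    chrom = normalize_chrom(chrom)
    values = [b.log2 for b in profile.bins if b.chrom == chrom]
    if not values:
        raise EmptyChromosomeError(
            f"{profile.sample_id}: no bins on chromosome {chrom}")
    return np.asarray(values, dtype=float)


def group_partition(n: int, g: int) -> List[Tuple[int, int]]:
    """Partition indices 0..n-1 into g contiguous half-open ranges.

    Index i is assigned to group floor(i*g/n), so the ranges are in order,
    cover 0..n-1 exactly once, and their sizes differ by at most one.
    """
    if g < 1:
        raise ValueError(f"need at least one group, got g={g}")
    if n < g:
        raise ValueError(f"insufficient bins: n={n} < g={g}")
    # group j spans [ceil(j*n/g), ceil((j+1)*n/g))
    bounds = [-(-j * n // g) for j in range(g + 1)]
    return [(bounds[j], bounds[j + 1]) for j in range(g)]


def reformat_signal(values: Sequence[float], target_len: int) -> np.ndarray:
    """Harmonize an ordered signal to a fixed length.

    Longer inputs are reduced by averaging contiguous groups from
    :func:`group_partition`; equal-length inputs pass through unchanged;
    shorter inputs are linearly interpolated onto ``target_len`` equally
    spaced points (a convenience path for small fixtures, logged as such).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("signal must be a non-empty 1-D sequence")
    n = v.size
    if n == target_len:
        return v.copy()
    if n > target_len:
        ranges = group_partition(n, target_len)
        sums = np.add.reduceat(v, [lo for lo, _ in ranges])
        sizes = np.array([hi - lo for lo, hi in ranges], dtype=float)
        return sums / sizes
    logger.warning(
        "signal of length %d upsampled to %d by linear interpolation", n,
        target_len)
    if n == 1:
        return np.full(target_len, v[0])
    return np.interp(np.linspace(0.0, n - 1.0, target_len), np.arange(n), v)


def featurize(
    profile: CnProfile,
    label: Optional[str] = None,
    target_len_chr1: int = CHR1_TARGET_LEN,
    target_len_chr19: int = CHR19_TARGET_LEN,
    clip: Optional[float] = 3.0,
) -> SampleFeatures:
    """Build the (x1, x2) fixed-length feature pair for one profile.

    ``clip`` bounds extreme log2 values to [-clip, +clip] before the model;
    pass ``None`` to disable.
    """
    x1 = reformat_signal(extract_chrom_signal(profile, "1"), target_len_chr1)
    x2 = reformat_signal(extract_chrom_signal(profile, "19"), target_len_chr19)
    if clip is not None:
        x1 = np.clip(x1, -clip, clip)
        x2 = np.clip(x2, -clip, clip)
    return SampleFeatures(
        sample_id=profile.sample_id,
        x1=FeatureVector("1", x1, target_len_chr1),
        x2=FeatureVector("19", x2, target_len_chr19),
        label=label,
    )


def _feature_columns(len1: int, len2: int) -> List[str]:
    return ([f"x1_{i + 1:04d}" for i in range(len1)]
            + [f"x2_{i + 1:04d}" for i in range(len2)])


def write_features(samples: Sequence[SampleFeatures], path) -> None:
    """Persist a feature matrix as TSV (sample_id, label, x1_*, x2_*)."""
    if not samples:
        raise ValueError("no samples to write")
    len1 = samples[0].x1.target_len
    len2 = samples[0].x2.target_len
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id,
               "label": s.label if s.label is not None else ""}
        row.update(zip(_feature_columns(len1, len2), s.concatenated))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_features(path) -> List[SampleFeatures]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    x1_cols = sorted(c for c in df.columns if c.startswith("x1_"))
    x2_cols = sorted(c for c in df.columns if c.startswith("x2_"))
    if not x1_cols or not x2_cols:
        raise ValueError(f"{path}: not a feature-matrix TSV")
    samples = []
    for _, row in df.iterrows():
        label = row.get("label")
        if pd.isna(label) or label == "":
            label = None
        samples.append(SampleFeatures(
            sample_id=str(row["sample_id"]),
            x1=FeatureVector("1", row[x1_cols].to_numpy(float), len(x1_cols)),
            x2=FeatureVector("19", row[x2_cols].to_numpy(float), len(x2_cols)),
            label=label,
        ))
    return samples
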