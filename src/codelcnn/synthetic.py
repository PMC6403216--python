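"""Simulator for labeled copy-number profiles.

Generates targeted-panel-sized (1869 chr1 / 649 chr19 bins) or dense
array-sized profiles with known arm-level truth: full 1p/19q deletions,
partial (sub-arm) deletions, single-arm events, per-bin Gaussian noise and
tumor-purity attenuation of the deletion shift.  This is the package's
self-contained test and demo data source.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .arm_caller import REGION_1P, REGION_19Q, ArmRegion
from .profile_io import (CnBin, CnProfile, LABEL_CODEL, LABEL_NO_CODEL,
                         write_array_probes, write_cnr)

__all__ = ["SimConfig", "SimTruth", "simulate_profile", "simulate_dataset",
           "write_dataset", "truth_label"]

CHR1_SIZE = 249_250_621   # hg19
CHR19_SIZE = 59_128_983

PANEL_BINS = {"1": 1869, "19": 649}
ARRAY_BINS = {"1": 30_000, "19": 12_000}

EVENT_NONE = "none"
EVENT_FULL = "full"
EVENT_PARTIAL = "partial"


@dataclass
class SimConfig:
    n_codel: int = 19
    n_control: int = 42
    platform: str = "panel"  # "panel" or "array"
    bins_chr1: Optional[int] = None   # platform default when None
    bins_chr19: Optional[int] = None
    del_shift: float = -0.6
    noise_sd: float = 0.15
    purity_range: Tuple[float, float] = (0.6, 1.0)
    partial_fraction: float = 0.1
    single_arm_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.platform not in ("panel", "array"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.n_codel < 0 or self.n_control < 0:
            raise ValueError("sample counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.del_shift > 0:
            raise ValueError("del_shift must be <= 0 (a deletion)")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity_range must satisfy 0 < low <= high <= 1")
        defaults = PANEL_BINS if self.platform == "panel" else ARRAY_BINS
        if self.bins_chr1 is None:
            self.bins_chr1 = defaults["1"]
        if self.bins_chr19 is None:
            self.bins_chr19 = defaults["19"]


@dataclass(frozen=True)
class SimTruth:
    sample_id: str
    event_1p: str = EVENT_NONE
    event_19q: str = EVENT_NONE
    purity: float = 1.0

    @property
    def codeletion(self) -> bool:
        return self.event_1p == EVENT_FULL and self.event_19q == EVENT_FULL


def truth_label(truth: SimTruth) -> str:
    return LABEL_CODEL if truth.codeletion else LABEL_NO_CODEL


def _attenuated_shift(del_shift: float, purity: float) -> float:
    """Observed log2 shift of a clonal deletion in a purity-diluted sample."""
    return float(np.log2(purity * 2.0 ** del_shift + (1.0 - purity)))


def _sample_rng(config: SimConfig, sample_id: str) -> np.random.Generator:
    return np.random.default_rng(
        (config.seed, zlib.crc32(sample_id.encode())))


def _tile(chrom_size: int, n_bins: int) -> Tuple[np.ndarray, np.ndarray]:
    edges = np.linspace(0, chrom_size, n_bins + 1).astype(int)
    return edges[:-1], edges[1:]


def _apply_event(log2: np.ndarray, mids: np.ndarray, region: ArmRegion,
                 event: str, shift: float, rng: np.random.Generator) -> None:
    in_region = (mids >= region.start - 1) & (mids < region.end)
    if event == EVENT_FULL:
        log2[in_region] += shift
    elif event == EVENT_PARTIAL:
        idx = np.flatnonzero(in_region)
        frac = rng.uniform(0.3, 0.6)
        width = max(1, int(round(frac * len(idx))))
        offset = rng.integers(0, len(idx) - width + 1)
        log2[idx[offset:offset + width]] += shift
    elif event != EVENT_NONE:
        raise ValueError(f"unknown event type {event!r}")


def simulate_profile(truth: SimTruth, config: SimConfig) -> CnProfile:
    """Render one truth record into a per-bin profile.

    Bins tile chr1 and chr19 uniformly; baseline log2 is Normal(0,
    noise_sd); arm events add the purity-attenuated deletion shift to every
    in-region bin (full) or to a random contiguous 30-60% sub-interval of
    the arm (partial).  Deterministic given (config.seed, sample_id).
    """
    rng = _sample_rng(config, truth.sample_id)
    shift = _attenuated_shift(config.del_shift, truth.purity)
    bins: List[CnBin] = []
    for chrom, size, n_bins, region, event in (
            ("1", CHR1_SIZE, config.bins_chr1, REGION_1P, truth.event_1p),
            ("19", CHR19_SIZE, config.bins_chr19, REGION_19Q, truth.event_19q)):
        starts, ends = _tile(size, n_bins)
        mids = 0.5 * (starts + ends)
        log2 = rng.normal(0.0, config.noise_sd, size=n_bins)
        _apply_event(log2, mids, region, event, shift, rng)
        bins.extend(
            CnBin(chrom=chrom, start=int(s), end=int(e), log2=float(v),
                  label=f"bin_{chrom}_{i}")
            for i, (s, e, v) in enumerate(zip(starts, ends, log2)))
    return CnProfile(sample_id=truth.sample_id, bins=bins)


def simulate_dataset(
    config: SimConfig,
) -> Tuple[List[CnProfile], List[SimTruth]]:
    """Simulate ``n_codel`` co-deleted and ``n_control`` control samples.

    Controls may carry a partial event (probability ``partial_fraction``)
    or a single-arm full deletion (``single_arm_fraction`` each for 1p-only
    and 19q-only) but never a full/full pair.  Reproducible under seed.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.purity_range
    truths: List[SimTruth] = []
    for i in range(config.n_codel):
        truths.append(SimTruth(
            sample_id=f"codel_{i + 1:03d}", event_1p=EVENT_FULL,
            event_19q=EVENT_FULL, purity=float(rng.uniform(lo, hi))))
    for i in range(config.n_control):
        purity = float(rng.uniform(lo, hi))
        u = rng.uniform()
        e1p, e19q = EVENT_NONE, EVENT_NONE
        if u < config.single_arm_fraction:
            e1p = EVENT_FULL
        elif u < 2 * config.single_arm_fraction:
            e19q = EVENT_FULL
        elif u < 2 * config.single_arm_fraction + config.partial_fraction:
            if rng.uniform() < 0.5:
                e1p = EVENT_PARTIAL
            else:
                e19q = EVENT_PARTIAL
        truths.append(SimTruth(sample_id=f"control_{i + 1:03d}",
                               event_1p=e1p, event_19q=e19q, purity=purity))
    profiles = [simulate_profile(t, config) for t in truths]
    return profiles, truths


def write_dataset(profiles: Sequence[CnProfile], truths: Sequence[SimTruth],
                  out_dir, platform: str = "panel") -> Path:
    """Emit per-sample profile files plus a truth TSV; returns the truth path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    writer = write_cnr if platform == "panel" else write_array_probes
    ext = "cnr" if platform == "panel" else "probes.tsv"
    for profile in profiles:
        writer(profile, out_dir / f"{profile.sample_id}.{ext}")
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("sample_id\tcodeletion\tevent_1p\tevent_19q\tpurity\n")
        for t in truths:
            fh.write(f"{t.sample_id}\t{str(t.codeletion).lower()}\t"
                     f"{t.event_1p}\t{t.event_19q}\t{t.purity:.4f}\n")
    return truth_path
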