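"""Reading and writing per-bin copy-number tables.

Two tab-delimited dialects are supported:

* the CNR dialect produced by targeted-panel copy-number pipelines
  (``chromosome  start  end  gene  log2  depth  weight``, the last three
  columns optional), and
* a minimal array-probe dialect (``chromosome  position  log2``).

Coordinates are stored 0-based half-open.  Chromosome names are normalized
by stripping a leading ``chr`` prefix on read and are never emitted with it.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple, Union

__all__ = [
    "CnBin",
    "CnProfile",
    "ParseError",
    "read_cnr",
    "write_cnr",
    "read_array_probes",
    "read_labels",
]

LABEL_CODEL = "codel"
LABEL_NO_CODEL = "no_codel"
VALID_LABELS = (LABEL_CODEL, LABEL_NO_CODEL)


class ParseError(ValueError):
    """Raised for malformed input tables; carries the offending line number."""

    def __init__(self, message: str, path: Union[str, Path, None] = None,
                 line: Union[int, None] = None):
        self.path = str(path) if path is not None else None
        self.line = line
        prefix = ""
        if self.path is not None:
            prefix += f"{self.path}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


def normalize_chrom(name: str) -> str:
    name = name.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if not name:
        raise ValueError("empty chromosome name")
    return name


def _chrom_sort_key(chrom: str) -> Tuple[int, int, str]:
    if chrom.isdigit():
        return (0, int(chrom), "")
    return (1, 0, chrom)


@dataclass(frozen=True)
class CnBin:
    """One genomic bin with a log2 copy ratio.

    ``start``/``end`` are 0-based half-open; ``weight`` is a non-negative
    confidence weight defaulting to 1.0.
    """

    chrom: str
    start: int
    end: int
    log2: float
    label: str = ""
    weight: float = 1.0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"bin {self.chrom}:{self.start}-{self.end}: start must be < end")
        if not math.isfinite(self.log2):
            raise ValueError(
                f"bin {self.chrom}:{self.start}-{self.end}: log2 must be finite")
        if self.weight < 0:
            raise ValueError(
                f"bin {self.chrom}:{self.start}-{self.end}: weight must be >= 0")

    @property
    def midpoint(self) -> float:
        """Bin midpoint on the 0-based axis."""
        return 0.5 * (self.start + self.end)


@dataclass
class CnProfile:
    """An ordered per-sample collection of bins.

    Bins are kept sorted by (chromosome, start).  Within each chromosome
    starts are strictly increasing and bins do not overlap; the resulting
    0-based relative order is the index used by the vectorization stage.
    """

    sample_id: str
    bins: List[CnBin] = field(default_factory=list)
    genome_build: str = "hg19"

    def __post_init__(self):
        self.bins = sorted(
            self.bins, key=lambda b: (_chrom_sort_key(b.chrom), b.start))
        prev = None
        for b in self.bins:
            if prev is not None and prev.chrom == b.chrom:
                if b.start == prev.start:
                    raise ValueError(
                        f"{self.sample_id}: duplicate bin start "
                        f"{b.chrom}:{b.start}")
                if b.start < prev.end:
                    raise ValueError(
                        f"{self.sample_id}: overlapping bins on {b.chrom} at "
                        f"{prev.start}-{prev.end} and {b.start}-{b.end}")
            prev = b

    def chroms(self) -> List[str]:
        seen: List[str] = []
        for b in self.bins:
            if not seen or seen[-1] != b.chrom:
                seen.append(b.chrom)
        return seen

    def bins_for(self, chrom: str) -> List[CnBin]:
        chrom = normalize_chrom(chrom)
        return [b for b in self.bins if b.chrom == chrom]

    def __len__(self) -> int:
        return len(self.bins)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CnProfile):
            return NotImplemented
        return (self.sample_id == other.sample_id
                and self.genome_build == other.genome_build
                and self.bins == other.bins)


def _float_field(raw: str, column: str, path, line: int) -> float:
    try:
        value = float(raw)
    except ValueError:
        raise ParseError(f"non-numeric {column} value {raw!r}", path, line) from None
    return value


def _int_field(raw: str, column: str, path, line: int) -> int:
    try:
        return int(raw)
    except ValueError:
        raise ParseError(f"non-integer {column} value {raw!r}", path, line) from None


def _read_table(path) -> Tuple[List[str], List[Tuple[int, List[str]]]]:
    with open(path, "r", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [(i + 1, row) for i, row in enumerate(reader) if row]
    if not rows:
        raise ParseError("empty file", path, None)
    header_line, header = rows[0]
    header = [h.strip().lower() for h in header]
    return header, rows[1:]


def read_cnr(path, sample_id: str) -> CnProfile:
    """Read a CNR-dialect table into a :class:`CnProfile`.

    Requires columns ``chromosome``, ``start``, ``end`` and ``log2``;
    ``gene`` and ``weight`` are used when present, ``depth`` is ignored.
    Rows may appear in any order; the profile is returned sorted.
    """
    header, rows = _read_table(path)
    required = ("chromosome", "start", "end", "log2")
    for col in required:
        if col not in header:
            raise ParseError(f"missing required column {col!r}", path, 1)
    idx = {name: header.index(name) for name in header}
    n_cols = len(header)

    bins = []
    for line, row in rows:
        if len(row) != n_cols:
            raise ParseError(
                f"expected {n_cols} fields, found {len(row)}", path, line)
        try:
            chrom = normalize_chrom(row[idx["chromosome"]])
        except ValueError as exc:
            raise ParseError(str(exc), path, line) from None
        start = _int_field(row[idx["start"]], "start", path, line)
        end = _int_field(row[idx["end"]], "end", path, line)
        log2 = _float_field(row[idx["log2"]], "log2", path, line)
        label = row[idx["gene"]].strip() if "gene" in idx else ""
        weight = (_float_field(row[idx["weight"]], "weight", path, line)
                  if "weight" in idx else 1.0)
        try:
            bins.append(CnBin(chrom=chrom, start=start, end=end, log2=log2,
                              label=label, weight=weight))
        except ValueError as exc:
            raise ParseError(str(exc), path, line) from None
    try:
        return CnProfile(sample_id=sample_id, bins=bins)
    except ValueError as exc:
        raise ParseError(str(exc), path, None) from None


def write_cnr(profile: CnProfile, path) -> None:
    """Write a profile in the CNR dialect (round-trips through read_cnr)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chromosome", "start", "end", "gene", "log2", "weight"])
        for b in profile.bins:
            writer.writerow(
                [b.chrom, b.start, b.end, b.label, f"{b.log2:.8g}",
                 f"{b.weight:.8g}"])


def read_array_probes(path, sample_id: str) -> CnProfile:
    """Read an array-probe table (``chromosome  position  log2``).

    Each probe becomes a unit-width bin (start=position, end=position+1).
    Duplicate positions on a chromosome are rejected.
    """
    header, rows = _read_table(path)
    for col in ("chromosome", "position", "log2"):
        if col not in header:
            raise ParseError(f"missing required column {col!r}", path, 1)
    idx = {name: header.index(name) for name in header}
    n_cols = len(header)

    bins = []
    for line, row in rows:
        if len(row) != n_cols:
            raise ParseError(
                f"expected {n_cols} fields, found {len(row)}", path, line)
        try:
            chrom = normalize_chrom(row[idx["chromosome"]])
        except ValueError as exc:
            raise ParseError(str(exc), path, line) from None
        pos = _int_field(row[idx["position"]], "position", path, line)
        log2 = _float_field(row[idx["log2"]], "log2", path, line)
        try:
            bins.append(CnBin(chrom=chrom, start=pos, end=pos + 1, log2=log2))
        except ValueError as exc:
            raise ParseError(str(exc), path, line) from None
    try:
        return CnProfile(sample_id=sample_id, bins=bins)
    except ValueError as exc:
        raise ParseError(str(exc), path, None) from None


def write_array_probes(profile: CnProfile, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chromosome", "position", "log2"])
        for b in profile.bins:
            writer.writerow([b.chrom, b.start, f"{b.log2:.8g}"])


def read_labels(path) -> Dict[str, str]:
    """Read a label sheet (``sample_id  label``), label in {codel, no_codel}."""
    header, rows = _read_table(path)
    for col in ("sample_id", "label"):
        if col not in header:
            raise ParseError(f"missing required column {col!r}", path, 1)
    idx = {name: header.index(name) for name in header}
    labels: Dict[str, str] = {}
    for line, row in rows:
        sid = row[idx["sample_id"]].strip()
        lab = row[idx["label"]].strip()
        if lab not in VALID_LABELS:
            raise ParseError(
                f"label must be one of {VALID_LABELS}, found {lab!r}",
                path, line)
        if sid in labels:
            raise ParseError(f"duplicate sample_id {sid!r}", path, line)
        labels[sid] = lab
    return labels
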