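"""Target-region (capture design) intervals and BED I/O.

Intervals are 0-based, half-open throughout, matching BED. Per-position
quantities elsewhere in the package (pileups, VCF) are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True, order=True)
class TargetRegion:
    """One capture target interval (typically an exon)."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    gene: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def total_target_bases(targets: Iterable[TargetRegion]) -> int:
    return sum(t.length for t in targets)


def sort_and_check_disjoint(targets: Sequence[TargetRegion]) -> list[TargetRegion]:
    """Sort targets; raise if any two on the same chromosome overlap."""
    out = sorted(targets, key=lambda t: (t.chrom, t.start, t.end))
    for a, b in zip(out, out[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"overlapping targets {a} / {b}")
    return out


class TargetIndex:
    """Sorted-array interval lookup over a disjoint target set.

    Supports vectorised point membership tests and span-overlap clipping;
    this is the coverage denominator used by depth and pileup code.
    """

    def __init__(self, targets: Sequence[TargetRegion]):
        self.targets = sort_and_check_disjoint(targets)
        tmp: dict[str, tuple[list[int], list[int]]] = {}
        for t in self.targets:
            s, e = tmp.setdefault(t.chrom, ([], []))
            s.append(t.start)
            e.append(t.end)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in tmp.items()
        }

    @property
    def total_bases(self) -> int:
        return total_target_bases(self.targets)

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: which 0-based positions fall inside a target."""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self._by_chrom:
            return np.zeros(positions.shape, dtype=bool)
        starts, ends = self._by_chrom[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        mask = np.zeros(positions.shape, dtype=bool)
        mask[ok] = positions[ok] < ends[idx[ok]]
        return mask

    def mask(self, chrom: str, length: int) -> np.ndarray:
        """Dense boolean target mask over [0, length) of one chromosome."""
        m = np.zeros(length, dtype=bool)
        starts, ends = self._by_chrom.get(chrom, (np.empty(0, np.int64),) * 2)
        for s, e in zip(starts, ends):
            m[s:e] = True
        return m

    def overlap_bases(self, chrom: str, start: int, end: int) -> int:
        """Number of bases of [start, end) inside targets."""
        if chrom not in self._by_chrom:
            return 0
        starts, ends = self._by_chrom[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        total = 0
        for i in range(lo, hi):
            total += max(0, min(end, ends[i]) - max(start, starts[i]))
        return total


def read_bed(path: str) -> list[TargetRegion]:
    """Read a BED3+ file into target regions (column 4 = name, used as gene)."""
    out: list[TargetRegion] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            name = parts[3] if len(parts) > 3 else ""
            out.append(
                TargetRegion(parts[0], int(parts[1]), int(parts[2]), gene=name, name=name)
            )
    return out


def write_bed(targets: Iterable[TargetRegion], path: str) -> None:
    with open(path, "w") as fh:
        for t in targets:
            name = t.gene or t.name
            if name:
                fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{name}\n")
            else:
                fh.write(f"{t.chrom}\t{t.start}\t{t.end}\n")
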