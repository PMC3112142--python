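"""Per-base depth over capture targets, coverage summaries and enrichment fold.

Depth counts the aligned spans of uniquely mapped reads (each mate
individually), clipped to target intervals. The headline mean fold uses
the read-bases / target-size definition, i.e. ``read_count * read_length /
total_target_bases``; the mean of per-base depths is exported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np

from .mapping import AcceptedPair, Alignment
from .regions import TargetIndex, TargetRegion


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (table-style), unlike banker's ``round``."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DepthTrack:
    """Dense per-base depth over one chromosome, with the target mask."""

    chrom: str
    depth: np.ndarray  # uint32 over the whole chromosome
    target_mask: np.ndarray  # bool, same length

    @property
    def target_depths(self) -> np.ndarray:
        return self.depth[self.target_mask]

    def fraction_covered(self, min_depth: int = 1) -> float:
        d = self.target_depths
        if len(d) == 0:
            raise ValueError("empty target set")
        return float((d >= min_depth).mean())


@dataclass
class CoverageSummary:
    mean_fold: float
    mean_fold_rounded: int
    mean_depth: float
    fraction_covered: float
    on_target_reads: int
    total_mapped_reads: int
    enrichment_fold: float | None = None


def _iter_alignments(alignments: Iterable[Alignment | AcceptedPair]):
    for a in alignments:
        if isinstance(a, AcceptedPair):
            yield a.alignment1
            yield a.alignment2
        else:
            yield a


def compute_depth(
    alignments: Iterable[Alignment | AcceptedPair],
    targets: Sequence[TargetRegion],
    reference_length: int,
    chrom: str | None = None,
) -> DepthTrack:
    """Per-base depth of unique alignments over one chromosome's targets."""
    index = TargetIndex(targets)
    if chrom is None:
        chrom = targets[0].chrom if targets else "chr1"
    mask = index.mask(chrom, reference_length)
    delta = np.zeros(reference_length + 1, dtype=np.int64)
    for a in _iter_alignments(alignments):
        if a.status != "unique":
            raise ValueError(f"non-unique alignment {a.read_id} in depth computation")
        if a.chrom != chrom:
            continue
        if a.pos < 0 or a.end > reference_length:
            raise ValueError(f"alignment {a.read_id} outside reference bounds")
        delta[a.pos] += 1
        delta[a.end] -= 1
    depth = np.cumsum(delta[:-1])
    depth[~mask] = 0  # depth is defined on target bases only
    return DepthTrack(chrom, depth.astype(np.uint32), mask)


def summarize_coverage(
    track: DepthTrack | None,
    targets: Sequence[TargetRegion],
    read_count: int,
    read_length: int,
    total_mapped_reads: int | None = None,
    min_depth: int = 1,
) -> CoverageSummary:
    """Coverage summary; ``read_count`` is the number of on-target unique reads.

    ``mean_fold`` = read_count * read_length / total target bases, reported
    rounded to the nearest integer (table precision). ``track`` may be None
    when only the formula-based summary is wanted.
    """
    total = sum(t.length for t in targets)
    if total <= 0:
        raise ValueError("zero-length target set")
    mean_fold = read_count * read_length / total
    if track is not None:
        mean_depth = float(track.target_depths.mean())
        frac = track.fraction_covered(min_depth)
    else:
        mean_depth = float("nan")
        frac = float("nan")
    return CoverageSummary(
        mean_fold=mean_fold,
        mean_fold_rounded=int(round_half_up(mean_fold)),
        mean_depth=mean_depth,
        fraction_covered=frac,
        on_target_reads=read_count,
        total_mapped_reads=total_mapped_reads if total_mapped_reads is not None else read_count,
    )


def enrichment_fold(
    on_target_reads: int,
    total_mapped_reads: int,
    target_size: int,
    genome_size: int,
) -> float:
    """Observed on-target fraction over the fraction expected at random.

    fold = (on_target/total) / (target_size/genome_size); 1.0 means no
    enrichment over uniform random sequencing.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    if not 0 < target_size <= genome_size:
        raise ValueError("need 0 < target_size <= genome_size")
    return (on_target_reads / total_mapped_reads) / (target_size / genome_size)


def count_on_target(
    alignments: Iterable[Alignment | AcceptedPair],
    targets: Sequence[TargetRegion],
) -> tuple[int, int]:
    """(on-target reads, total reads); a read is on-target if its span overlaps."""
    index = TargetIndex(targets)
    on = total = 0
    for a in _iter_alignments(alignments):
        total += 1
        if index.overlap_bases(a.chrom, a.pos, a.end) > 0:
            on += 1
    return on, total


def write_bedgraph(track: DepthTrack, path: str) -> None:
    """Depth over target bases as BEDGraph (constant-depth runs merged)."""
    with open(path, "w") as fh:
        d = track.depth
        m = track.target_mask
        boundaries = np.flatnonzero(
            np.diff(m.astype(np.int8), prepend=0, append=0) != 0
        ).reshape(-1, 2)
        for s, e in boundaries:
            run_start = s
            for i in range(s + 1, e + 1):
                if i == e or d[i] != d[run_start]:
                    fh.write(f"{track.chrom}\t{run_start}\t{i}\t{int(d[run_start])}\n")
                    run_start = i


def exon_depth_table(track: DepthTrack, targets: Sequence[TargetRegion]):
    """Long-format per-base depth per exon (plot-ready data for depth figures)."""
    import pandas as pd

    rows = []
    for t in targets:
        for pos in range(t.start, t.end):
            rows.append((t.gene or t.name, t.name, pos + 1, int(track.depth[pos])))
    return pd.DataFrame(rows, columns=["gene", "exon", "pos", "depth"])
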