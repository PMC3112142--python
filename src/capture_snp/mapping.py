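"""Read QC, unique ungapped mapping (<=3 mismatches) and pair acceptance.

The mapper performs an exhaustive ungapped scan of both strands for
placements within a Hamming-distance budget (default 3, with N in a read
mismatching every reference base). For speed it uses a k-mer seed index
with 4-segment pigeonholing: any placement with <=3 mismatches matches at
least one of 4 disjoint read segments exactly, so verifying all seed hits
is equivalent to the full scan. Reads too short for 4 seeds fall back to
the literal all-offsets scan.

A read is ``unique`` only if a single placement achieves the minimal
mismatch count; a tie at the minimum makes it ``multi`` (best-stratum
semantics; ``strict`` mode instead flags any second placement within the
budget). Multi-mapped reads are excluded from all downstream counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .simulate import revcomp

# A,C,G,T -> 0..3; read N -> 4, reference N -> 5 so N never matches anything
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_REF_CODE = _CODE.copy()
_REF_CODE[ord("N")] = 5
_REF_CODE[ord("n")] = 5


def encode_read(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_reference(seq: str) -> np.ndarray:
    return _REF_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: str = ""
    qual2: str = ""

    def __post_init__(self) -> None:
        for seq, qual in ((self.seq1, self.qual1), (self.seq2, self.qual2)):
            if qual and len(qual) != len(seq):
                raise ValueError(f"read {self.id}: sequence/quality length mismatch")
            if set(seq) - set("ACGTNacgtn"):
                raise ValueError(f"read {self.id}: non-ACGTN characters")


@dataclass
class Alignment:
    read_id: str
    chrom: str
    pos: int  # 0-based leftmost, -1 if unmapped/multi
    strand: str  # '+', '-' or '.'
    mismatches: int
    status: str  # unique | multi | unmapped
    length: int
    seq: str = ""  # read sequence as sequenced (not reference-oriented)

    @property
    def end(self) -> int:
        return self.pos + self.length

    def aligned_bases(self) -> str:
        """Read bases in reference orientation."""
        return self.seq if self.strand == "+" else revcomp(self.seq)


@dataclass
class AcceptedPair:
    alignment1: Alignment
    alignment2: Alignment
    fragment_length: int


def read_fastq_pairs(path1: str, path2: str) -> list[ReadPair]:
    """Load two synchronized FASTQ files as read pairs."""
    from Bio import SeqIO

    pairs: list[ReadPair] = []
    it1 = SeqIO.parse(path1, "fastq")
    it2 = SeqIO.parse(path2, "fastq")
    for i, (r1, r2) in enumerate(zip(it1, it2)):
        rid = r1.id.rsplit("/", 1)[0]
        rid2 = r2.id.rsplit("/", 1)[0]
        if rid != rid2:
            raise ValueError(f"record {i}: mate ids differ ({r1.id} vs {r2.id})")
        q1 = "".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"])
        pairs.append(ReadPair(rid, str(r1.seq).upper(), str(r2.seq).upper(), q1, q2))
    return pairs


def filter_ambiguous(pairs: Iterable[ReadPair], max_n: int = 2):
    """Drop pairs where either mate has more than ``max_n`` ambiguous (N) calls.

    The published filter removes reads with 3 or more N; downstream logic is
    pair-based, so the whole pair is dropped when either mate fails.
    Returns (kept_pairs, removed_pair_count).
    """
    kept: list[ReadPair] = []
    removed = 0
    for p in pairs:
        if p.seq1.count("N") > max_n or p.seq2.count("N") > max_n:
            removed += 1
        else:
            kept.append(p)
    return kept, removed


class ReferenceIndex:
    """k-mer seed index over one reference contig for the ungapped mapper."""

    def __init__(self, sequence: str, chrom: str = "chr1", seed_len: int = 12):
        self.chrom = chrom
        self.sequence = sequence
        self.codes = encode_reference(sequence)
        self.seed_len = seed_len
        self._powers = 4 ** np.arange(seed_len - 1, -1, -1, dtype=np.int64)
        n_kmers = len(sequence) - seed_len + 1
        if n_kmers <= 0:
            self._sorted_hashes = np.empty(0, dtype=np.int64)
            self._sorted_pos = np.empty(0, dtype=np.int64)
            return
        windows = np.lib.stride_tricks.sliding_window_view(self.codes, seed_len)
        valid = (windows < 4).all(axis=1)
        hashes = windows.astype(np.int64) @ self._powers
        hashes[~valid] = -1
        order = np.argsort(hashes, kind="stable")
        self._sorted_hashes = hashes[order]
        self._sorted_pos = order.astype(np.int64)

    def __len__(self) -> int:
        return len(self.sequence)

    def seed_hits(self, hashes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """For an array of seed hashes return (query_idx, ref_pos) hit pairs."""
        lo = np.searchsorted(self._sorted_hashes, hashes, side="left")
        hi = np.searchsorted(self._sorted_hashes, hashes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        qidx = np.repeat(np.arange(len(hashes)), counts)
        if total == 0:
            return qidx, np.empty(0, dtype=np.int64)
        # vectorised concatenation of the ranges [lo_i, hi_i)
        starts = np.cumsum(counts) - counts
        offsets = np.repeat(lo, counts) + np.arange(total) - np.repeat(starts, counts)
        return qidx, self._sorted_pos[offsets]


def _hamming_at(index: ReferenceIndex, query_codes: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Mismatch counts of one encoded query at the given reference offsets."""
    L = len(query_codes)
    windows = np.lib.stride_tricks.sliding_window_view(index.codes, L)
    return (windows[positions] != query_codes).sum(axis=1)


def map_reads(
    seqs: Sequence[str],
    index: ReferenceIndex,
    read_ids: Sequence[str] | None = None,
    max_mismatches: int = 3,
    strict: bool = False,
) -> list[Alignment]:
    """Map many same-length reads; vectorised batch version of :func:`map_read`."""
    if not seqs:
        return []
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("batch mapping requires equal-length reads")
    if read_ids is None:
        read_ids = [f"read{i}" for i in range(len(seqs))]
    if L < 4 * index.seed_len or L > len(index):
        return [
            map_read(s, index, read_id=r, max_mismatches=max_mismatches, strict=strict)
            for s, r in zip(seqs, read_ids)
        ]

    n = len(seqs)
    fwd = np.vstack([encode_read(s) for s in seqs])
    rev = np.vstack([encode_read(revcomp(s)) for s in seqs])

    cand_read: list[np.ndarray] = []
    cand_pos: list[np.ndarray] = []
    cand_strand: list[np.ndarray] = []
    s = index.seed_len
    chunk_offsets = [0, s, 2 * s, 3 * s]
    for strand_code, mat in ((0, fwd), (1, rev)):
        for off in chunk_offsets:
            chunk = mat[:, off:off + s]
            ok = (chunk < 4).all(axis=1)
            hashes = chunk.astype(np.int64) @ index._powers
            hashes[~ok] = -2  # never present in index
            qidx, rpos = index.seed_hits(hashes)
            start = rpos - off
            keep = (start >= 0) & (start + L <= len(index))
            cand_read.append(qidx[keep])
            cand_pos.append(start[keep])
            cand_strand.append(np.full(keep.sum(), strand_code, dtype=np.int8))

    read_idx = np.concatenate(cand_read)
    pos = np.concatenate(cand_pos)
    strand = np.concatenate(cand_strand)
    # dedupe candidate placements
    key = (read_idx.astype(np.int64) * 2 + strand) * (len(index) + 1) + pos
    _, first = np.unique(key, return_index=True)
    read_idx, pos, strand = read_idx[first], pos[first], strand[first]

    # verify candidates in chunks to bound memory
    mm = np.empty(len(pos), dtype=np.int32)
    windows = np.lib.stride_tricks.sliding_window_view(index.codes, L)
    CHUNK = 1 << 18
    for lo in range(0, len(pos), CHUNK):
        sl = slice(lo, min(lo + CHUNK, len(pos)))
        q = np.where(strand[sl, None] == 0, fwd[read_idx[sl]], rev[read_idx[sl]])
        mm[sl] = (windows[pos[sl]] != q).sum(axis=1)

    ok = mm <= max_mismatches
    read_idx, pos, strand, mm = read_idx[ok], pos[ok], strand[ok], mm[ok]

    results: list[Alignment] = [
        Alignment(rid, index.chrom, -1, ".", 0, "unmapped", L, seq)
        for rid, seq in zip(read_ids, seqs)
    ]
    if len(read_idx) == 0:
        return results
    order = np.lexsort((pos, strand, mm, read_idx))
    read_idx, pos, strand, mm = read_idx[order], pos[order], strand[order], mm[order]
    starts = np.flatnonzero(np.diff(read_idx, prepend=-1))
    bounds = np.append(starts, len(read_idx))
    for k, b in enumerate(starts):
        r = int(read_idx[b])
        best = int(mm[b])
        group_end = int(bounds[k + 1])
        if strict:
            n_best = group_end - b
        else:
            n_best = int(np.searchsorted(mm[b:group_end], best, side="right"))
        status = "unique" if n_best == 1 else "multi"
        a = results[r]
        if status == "unique":
            a.pos = int(pos[b])
            a.strand = "+" if strand[b] == 0 else "-"
            a.mismatches = best
        a.status = status
    return results


def map_read(
    seq: str,
    index: ReferenceIndex,
    read_id: str = "read",
    max_mismatches: int = 3,
    strict: bool = False,
) -> Alignment:
    """Map one read against the indexed reference.

    Equivalent to scanning every offset on both strands for ungapped
    placements with Hamming distance <= ``max_mismatches``. Reads longer
    than the reference are reported unmapped.
    """
    L = len(seq)
    if L > len(index):
        return Alignment(read_id, index.chrom, -1, ".", 0, "unmapped", L, seq)
    if L >= 4 * index.seed_len:
        return map_reads([seq], index, [read_id], max_mismatches, strict)[0]
    # short-read fallback: literal exhaustive scan
    windows = np.lib.stride_tricks.sliding_window_view(index.codes, L)
    placements: list[tuple[int, int, int]] = []  # (mm, strand_code, pos)
    for strand_code, q in ((0, encode_read(seq)), (1, encode_read(revcomp(seq)))):
        mm = (windows != q).sum(axis=1)
        for p in np.flatnonzero(mm <= max_mismatches).tolist():
            placements.append((int(mm[p]), strand_code, p))
    if not placements:
        return Alignment(read_id, index.chrom, -1, ".", 0, "unmapped", L, seq)
    placements.sort()
    best = placements[0][0]
    n_best = len(placements) if strict else sum(1 for m, *_ in placements if m == best)
    if n_best > 1:
        return Alignment(read_id, index.chrom, -1, ".", best, "multi", L, seq)
    m, sc, p = placements[0]
    return Alignment(read_id, index.chrom, p, "+" if sc == 0 else "-", m, "unique", L, seq)


REJECTION_REASONS = ("non_unique", "diff_chrom", "same_strand", "outward",
                     "too_short", "too_long")


def pair_filter(
    a1: Alignment,
    a2: Alignment,
    min_fragment: int = 100,
    max_fragment: int = 500,
):
    """Accept a mate pair if FR-oriented with outer fragment in [100, 500] bp.

    The fragment length is outer: from the + strand mate's first base to the
    - strand mate's last base, inclusive. Bounds are inclusive. Returns an
    :class:`AcceptedPair` or a rejection-reason string.
    """
    if a1.status != "unique" or a2.status != "unique":
        return "non_unique"
    if a1.chrom != a2.chrom:
        return "diff_chrom"
    if a1.strand == a2.strand:
        return "same_strand"
    plus, minus = (a1, a2) if a1.strand == "+" else (a2, a1)
    if plus.pos > minus.pos:
        return "outward"
    fragment = minus.end - plus.pos
    if fragment < min_fragment:
        return "too_short"
    if fragment > max_fragment:
        return "too_long"
    return AcceptedPair(a1, a2, fragment)


def accept_pairs(
    alignments1: Sequence[Alignment],
    alignments2: Sequence[Alignment],
    min_fragment: int = 100,
    max_fragment: int = 500,
):
    """Pair up two alignment lists; returns (accepted, rejection counts)."""
    accepted: list[AcceptedPair] = []
    reasons = {r: 0 for r in REJECTION_REASONS}
    for a1, a2 in zip(alignments1, alignments2):
        res = pair_filter(a1, a2, min_fragment, max_fragment)
        if isinstance(res, AcceptedPair):
            accepted.append(res)
        else:
            reasons[res] += 1
    return accepted, reasons


def read_sam(path: str, default_length: int = 50) -> list[Alignment]:
    """Ingest alignments from a SAM file produced by an external aligner.

    Primary mapped records become alignments (SAM 1-based POS converted to
    0-based); secondary/supplementary records and records with mapping
    quality 0 are marked ``multi``; unmapped records ``unmapped``. Mismatch
    counts are taken from the NM tag when present.
    """
    import pysam

    out: list[Alignment] = []
    try:
        sam = pysam.AlignmentFile(path, "r")
    except ValueError as e:
        raise ValueError(f"{path}: SAM has no @SQ header lines") from e
    with sam:
        if not sam.header.get("SQ"):
            raise ValueError(f"{path}: SAM has no @SQ header lines")
        lengths = {r: l for r, l in zip(sam.references, sam.lengths)}
        for rec in sam:
            seq = rec.query_sequence or ""
            length = len(seq) or rec.query_length or default_length
            if rec.is_unmapped:
                out.append(Alignment(rec.query_name, "*", -1, ".", 0,
                                     "unmapped", length, seq))
                continue
            chrom = rec.reference_name
            if rec.reference_start >= lengths[chrom]:
                raise ValueError(
                    f"{path}: {rec.query_name} at {chrom}:{rec.reference_start} "
                    "beyond reference end")
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            status = "multi" if (rec.is_secondary or rec.is_supplementary
                                 or rec.mapping_quality == 0) else "unique"
            out.append(Alignment(rec.query_name, chrom, rec.reference_start,
                                 "-" if rec.is_reverse else "+", int(nm),
                                 status, length, seq))
    return out
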