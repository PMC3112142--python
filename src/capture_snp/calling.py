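"""Strand-split pileup construction and threshold-based diploid genotyping.

Each covered target base yields a pileup column of per-base counts split
by alignment strand ("forward;reverse"). A site is called heterozygous
when the second-ranked allele reaches ``het_min_fraction`` (default 0.20)
of the column depth, otherwise homozygous for the top allele. Calls carry
a coverage-confidence tier: depth > 50 is high confidence, depth < 10 is
removed, 10-50 is low confidence.

The caller is a calibrated reconstruction of a commercial caller's
behaviour from its published calls: the published extreme minor fractions
(0.172 called homozygous, 0.254 called heterozygous) bound the threshold,
and 0.20 sits inside that window. Calling is symmetric in the two strand
counts, so the forward;reverse order convention never affects a genotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .mapping import AcceptedPair, Alignment, encode_read
from .regions import TargetIndex, TargetRegion

_BASE_ORDER = "ACGT"


class TriallelicWarning(UserWarning):
    """More than two alleles observed in one pileup column."""


@dataclass
class PileupColumn:
    """Strand-split base counts at one position (1-based)."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def total(self, base: str) -> int:
        f, r = self.counts.get(base, (0, 0))
        return f + r

    @property
    def depth(self) -> int:
        return sum(f + r for f, r in self.counts.values())

    def counts_row(self) -> list[str]:
        """Table-style 'fwd;rev' cells in A,C,G,T order."""
        return [f"{self.counts.get(b, (0, 0))[0]};{self.counts.get(b, (0, 0))[1]}"
                for b in _BASE_ORDER]


@dataclass
class GenotypeCall:
    chrom: str
    pos: int  # 1-based
    ref_base: str
    genotype: tuple[str, str]  # unordered pair, stored sorted
    zygosity: str  # hom_ref | het | hom_alt
    depth: int
    minor_fraction: float
    confidence: str = ""  # high | low, set by confidence_filter

    @property
    def alleles(self) -> frozenset:
        return frozenset(self.genotype)

    @property
    def is_het(self) -> bool:
        return self.zygosity == "het"


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: tuple[str, ...]
    sample_id: str
    zygosity: str
    depth: int
    confidence: str
    genotype: tuple[str, str]
    gene: str = ""
    rsid: str = ""

    @property
    def key(self) -> tuple:
        """Allele-aware identity key used for all set operations."""
        return (self.chrom, self.pos, self.alt)

    @property
    def g_notation(self) -> str:
        return "; ".join(f"g.{self.pos}{self.ref}>{a}" for a in self.alt)


def build_pileup(
    alignments: Iterable[Alignment | AcceptedPair],
    reference: str,
    targets: Sequence[TargetRegion],
    chrom: str | None = None,
) -> list[PileupColumn]:
    """Pileup columns for every covered target base, from unique alignments.

    Each read contributes its (reference-oriented) base at every position it
    covers, tallied under its alignment strand; N bases are not counted.
    """
    index = TargetIndex(targets)
    if chrom is None:
        chrom = targets[0].chrom if targets else "chr1"
    L = len(reference)
    mask = index.mask(chrom, L)
    counts = np.zeros((4, 2, L), dtype=np.uint32)

    pos_chunks: list[np.ndarray] = []
    base_chunks: list[np.ndarray] = []
    strand_chunks: list[np.ndarray] = []
    for a in _flatten(alignments):
        if a.status != "unique":
            raise ValueError(f"non-unique alignment {a.read_id} in pileup")
        if a.chrom != chrom:
            raise ValueError(
                f"alignment chrom {a.chrom} inconsistent with reference chrom {chrom}")
        codes = encode_read(a.aligned_bases())
        positions = np.arange(a.pos, a.end)
        keep = (codes < 4) & mask[positions]
        pos_chunks.append(positions[keep])
        base_chunks.append(codes[keep])
        strand_chunks.append(
            np.full(int(keep.sum()), 0 if a.strand == "+" else 1, dtype=np.int8))

    if pos_chunks:
        allpos = np.concatenate(pos_chunks)
        allbase = np.concatenate(base_chunks).astype(np.int64)
        allstrand = np.concatenate(strand_chunks).astype(np.int64)
        flat = (allbase * 2 + allstrand) * L + allpos
        np.add.at(counts.reshape(-1), flat, 1)

    covered = np.flatnonzero(counts.sum(axis=(0, 1)) > 0)
    columns: list[PileupColumn] = []
    for p in covered.tolist():
        col = PileupColumn(chrom, p + 1, reference[p])
        for bi, b in enumerate(_BASE_ORDER):
            f, r = int(counts[bi, 0, p]), int(counts[bi, 1, p])
            if f or r:
                col.counts[b] = (f, r)
        columns.append(col)
    return columns


def _flatten(alignments):
    for a in alignments:
        if isinstance(a, AcceptedPair):
            yield a.alignment1
            yield a.alignment2
        else:
            yield a


def call_genotype(column: PileupColumn, het_min_fraction: float = 0.20) -> GenotypeCall:
    """Diploid genotype from one strand-split pileup column.

    Alleles are ranked by total (forward+reverse) count; the site is het
    when second_count / depth >= ``het_min_fraction``, otherwise homozygous
    for the top allele. Depth 0 raises (no-call).
    """
    depth = column.depth
    if depth < 1:
        raise ValueError(f"no-call: zero depth at {column.chrom}:{column.pos}")
    totals = sorted(
        ((column.total(b), b) for b in _BASE_ORDER if column.total(b) > 0),
        key=lambda t: (-t[0], t[1]),
    )
    if len(totals) > 2:
        warnings.warn(
            f"{column.chrom}:{column.pos}: {len(totals)} alleles observed; "
            "calling from the top two", TriallelicWarning, stacklevel=2)
    top_count, top = totals[0]
    second_count = totals[1][0] if len(totals) > 1 else 0
    second = totals[1][1] if len(totals) > 1 else top
    minor_fraction = second_count / depth
    if minor_fraction >= het_min_fraction:
        genotype = tuple(sorted((top, second)))
        zygosity = "het"
    else:
        genotype = (top, top)
        zygosity = "hom_ref" if top == column.ref_base else "hom_alt"
    return GenotypeCall(column.chrom, column.pos, column.ref_base, genotype,
                        zygosity, depth, minor_fraction)


def confidence_filter(
    calls: Iterable[GenotypeCall],
    drop_below: int = 10,
    high_above: int = 50,
):
    """Remove calls with depth < ``drop_below``; tier the rest by depth.

    Depth strictly above ``high_above`` is high confidence; the inclusive
    band [drop_below, high_above] is low confidence. Returns
    (kept calls, removed count).
    """
    kept: list[GenotypeCall] = []
    removed = 0
    for c in calls:
        if c.depth < drop_below:
            removed += 1
            continue
        c.confidence = "high" if c.depth > high_above else "low"
        kept.append(c)
    return kept, removed


def emit_variants(
    calls: Iterable[GenotypeCall],
    sample_id: str,
    gene_of: "callable | None" = None,
) -> list[VariantRecord]:
    """Variant records for every non-hom_ref call (one record per site)."""
    records: list[VariantRecord] = []
    for c in calls:
        if c.zygosity == "hom_ref":
            continue
        alt = tuple(sorted(set(c.genotype) - {c.ref_base}))
        if not alt:  # het of two non-ref alleles handled above; defensive
            continue
        gene = gene_of(c.chrom, c.pos) if gene_of else ""
        records.append(VariantRecord(c.chrom, c.pos, c.ref_base, alt, sample_id,
                                     c.zygosity, c.depth, c.confidence,
                                     c.genotype, gene=gene))
    return records


def gene_lookup(targets: Sequence[TargetRegion]):
    """Callable (chrom, 1-based pos) -> gene name from the target design."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for t in sorted(targets, key=lambda t: (t.chrom, t.start)):
        s, e, g = by_chrom.setdefault(t.chrom, ([], [], []))  # type: ignore[arg-type]
        s.append(t.start)
        e.append(t.end)
        g.append(t.gene)
    by_chrom = {c: (np.asarray(s), np.asarray(e), g) for c, (s, e, g) in by_chrom.items()}

    def lookup(chrom: str, pos1: int) -> str:
        if chrom not in by_chrom:
            return ""
        starts, ends, genes = by_chrom[chrom]
        i = int(np.searchsorted(starts, pos1 - 1, side="right")) - 1
        if i >= 0 and pos1 - 1 < ends[i]:
            return genes[i]
        return ""

    return lookup


# ---------------------------------------------------------------------------
# output formats


def write_vcf(records: Sequence[VariantRecord], path: str, contigs: dict[str, int],
              sample_id: str | None = None) -> None:
    """Minimal single-sample VCF v4.2 (DP info, GT per sample)."""
    sample = sample_id or (records[0].sample_id if records else "SAMPLE")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FILTER=<ID=low_conf,Description="Coverage 10-50">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            alt = ",".join(r.alt)
            alleles = [r.ref] + list(r.alt)
            gt = "/".join(str(alleles.index(a)) for a in sorted(r.genotype))
            filt = "PASS" if r.confidence == "high" else "low_conf"
            rid = r.rsid or "."
            fh.write(f"{r.chrom}\t{r.pos}\t{rid}\t{r.ref}\t{alt}\t.\t{filt}\t"
                     f"DP={r.depth}\tGT\t{gt}\n")


def write_pileup_tsv(columns: Sequence[PileupColumn], path: str,
                     calls: dict[int, GenotypeCall] | None = None) -> None:
    """Table-style TSV with strand-split 'fwd;rev' counts per base."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\tcoverage\tA\tC\tG\tT\tgenotype\n")
        for col in columns:
            geno = ""
            if calls and col.pos in calls:
                geno = "".join(calls[col.pos].genotype)
            cells = "\t".join(col.counts_row())
            fh.write(f"{col.chrom}\t{col.pos}\t{col.ref_base}\t{col.depth}\t{cells}\t{geno}\n")


def parse_strand_counts(cell: str) -> tuple[int, int]:
    """Parse one 'forward;reverse' count cell."""
    f, r = cell.split(";")
    return int(f), int(r)


def column_from_counts(chrom: str, pos: int, ref: str,
                       cells: dict[str, str]) -> PileupColumn:
    """Build a pileup column from table-style 'f;r' cells keyed by base."""
    col = PileupColumn(chrom, pos, ref)
    for base, cell in cells.items():
        f, r = parse_strand_counts(cell)
        if f or r:
            col.counts[base] = (f, r)
    return col
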