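"""Synthetic hybridization-capture experiment with known ground truth.

Emulates a targeted-enrichment study of matched tumor/leukocyte pairs:
a reference with exonic capture targets, 50-mer probe tiling, planted
germline SNPs, tumor loss-of-heterozygosity (LOH) events converting
heterozygous sites to homozygous, and 50 bp FR paired-end reads with
100-500 bp outer fragments, sequencing errors, N-call artifacts, an
off-target read fraction and multi-mapping decoy duplications.

All randomness flows through a single ``numpy.random.Generator`` seeded
from ``SimConfig.seed``; the order of draws is fixed (reference bases,
exon geometry, decoys, variants, then reads), so outputs are
byte-reproducible for a given configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .regions import TargetRegion, TargetIndex, total_target_bases

BASES = np.array(list("ACGT"))
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: chromosome name used for all simulated contigs
SIM_CHROM = "chr1"


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class ConfigurationError(ValueError):
    """Raised when a SimConfig cannot produce the requested design."""


@dataclass
class SimConfig:
    """Parameters of one simulated capture experiment.

    Defaults emulate the scale of a two-patient exome-panel study scaled
    to a single-machine run: a 0.5 Mb reference with ~23% of it in exonic
    targets (the ratio of a 504 kb core target to a 2.2 Mb design region),
    germline SNPs at 2.6 per target kb, and 50 bp paired-end reads with
    100-500 bp outer fragments.
    """

    reference_length: int = 500_000
    n_genes: int = 40
    exons_per_gene: int = 8
    exon_length_range: tuple[int, int] = (120, 600)
    target_fraction: float = 0.23
    snp_density: float = 2.6  # variants per kb of target
    het_fraction: float = 0.6
    loh_fraction: float = 0.05
    read_length: int = 50
    insert_range: tuple[int, int] = (100, 500)
    n_read_pairs: int = 150_000
    error_rate: float = 0.005
    n_artifact_rate: float = 0.02
    off_target_fraction: float = 0.3
    decoy_duplications: int = 0
    decoy_length: int = 300
    seed: int = 0

    def validate(self) -> None:
        for name in ("target_fraction", "het_fraction", "loh_fraction",
                     "error_rate", "n_artifact_rate", "off_target_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} not in [0,1]")
        if self.insert_range[0] > self.insert_range[1]:
            raise ConfigurationError("insert_range min > max")
        if self.insert_range[0] < self.read_length:
            raise ConfigurationError("insert shorter than one read")
        lo, hi = self.exon_length_range
        if lo > hi or lo < 1:
            raise ConfigurationError("bad exon_length_range")
        n_exons = self.n_genes * self.exons_per_gene
        if n_exons * hi > self.reference_length:
            raise ConfigurationError("reference too short for requested exon geometry")
        want = self.target_fraction * self.reference_length
        if not n_exons * lo * 0.9 <= want <= n_exons * hi * 1.1:
            raise ConfigurationError(
                f"target_fraction {self.target_fraction} infeasible for "
                f"{n_exons} exons of {lo}-{hi} bp on {self.reference_length} bp"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Planted state of one simulated patient.

    ``germline_genotypes``/``tumor_genotypes`` map 0-based position to an
    unordered diploid allele pair (stored sorted); ``loh_events`` are the
    positions heterozygous in germline but homozygous in tumor;
    ``read_origin`` maps read-pair id to (true fragment start, on-target
    flag) and covers every emitted pair.
    """

    ref_alleles: dict[int, str] = field(default_factory=dict)
    germline_genotypes: dict[int, tuple[str, str]] = field(default_factory=dict)
    tumor_genotypes: dict[int, tuple[str, str]] = field(default_factory=dict)
    loh_events: set[int] = field(default_factory=set)
    read_origin: dict[str, tuple[int, bool]] = field(default_factory=dict)

    def genotypes(self, tissue: str) -> dict[int, tuple[str, str]]:
        if tissue in ("normal", "leukocyte", "leuko"):
            return self.germline_genotypes
        if tissue == "tumor":
            return self.tumor_genotypes
        raise ValueError(f"unknown tissue {tissue!r}")


@dataclass(frozen=True)
class Probe:
    """One 50-mer capture probe; consecutive probes on an exon alternate strand."""

    chrom: str
    start: int
    length: int = 50
    strand: str = "+"


@dataclass
class SimulatedReference:
    sequence: str
    chrom: str
    targets: list[TargetRegion]
    decoys: list[tuple[int, int, int]]  # (source_start, dest_start, length)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def generate_reference(config: SimConfig) -> SimulatedReference:
    """Random reference with gene/exon structure giving ~target_fraction in exons.

    Genes are laid out left to right with random intergenic gaps; each gene
    holds ``exons_per_gene`` exons whose lengths are drawn from
    ``exon_length_range`` and then rescaled so the summed exon length matches
    ``target_fraction * reference_length``. Decoy duplications copy target
    segments into off-target sequence so reads from them become multi-mappers.
    """
    config.validate()
    rng = config.rng()
    seq = rng.integers(0, 4, size=config.reference_length, dtype=np.int8)

    n_exons = config.n_genes * config.exons_per_gene
    lo, hi = config.exon_length_range
    lengths = rng.integers(lo, hi + 1, size=n_exons).astype(float)
    want = config.target_fraction * config.reference_length
    lengths = np.clip(np.round(lengths * want / lengths.sum()), lo, hi).astype(int)

    total_exonic = int(lengths.sum())
    spare = config.reference_length - total_exonic
    if spare < n_exons:  # need at least 1 bp between exons
        raise ConfigurationError("exons do not fit in reference")
    # random gap before each exon plus a terminal gap, all >=1
    gaps = rng.multinomial(spare - (n_exons + 1), np.full(n_exons + 1, 1.0 / (n_exons + 1))) + 1

    targets: list[TargetRegion] = []
    pos = 0
    for i in range(n_exons):
        pos += int(gaps[i])
        gene = f"GENE{i // config.exons_per_gene + 1:03d}"
        exon = i % config.exons_per_gene + 1
        targets.append(
            TargetRegion(SIM_CHROM, pos, pos + int(lengths[i]),
                         gene=gene, name=f"{gene}_ex{exon}")
        )
        pos += int(lengths[i])

    achieved = total_target_bases(targets) / config.reference_length
    if abs(achieved - config.target_fraction) > 0.1 * config.target_fraction:
        raise ConfigurationError(
            f"achieved target fraction {achieved:.4f} deviates >10% from "
            f"{config.target_fraction}"
        )

    decoys: list[tuple[int, int, int]] = []
    if config.decoy_duplications:
        index = TargetIndex(targets)
        mask = index.mask(SIM_CHROM, config.reference_length)
        for _ in range(config.decoy_duplications):
            src_region = targets[rng.integers(0, len(targets))]
            length = min(config.decoy_length, src_region.length)
            src = int(rng.integers(src_region.start, src_region.end - length + 1))
            for _attempt in range(100):
                dest = int(rng.integers(0, config.reference_length - length))
                window = mask[dest:dest + length]
                if not window.any():
                    break
            else:  # pragma: no cover - pathological geometry
                raise ConfigurationError("no off-target space for decoy")
            seq[dest:dest + length] = seq[src:src + length]
            decoys.append((src, dest, length))

    return SimulatedReference("".join(BASES[seq]), SIM_CHROM, targets, decoys)


def design_probes(
    targets: Sequence[TargetRegion],
    step: int = 11,
    min_probes_per_exon: int = 20,
    probe_length: int = 50,
    reference_length: int | None = None,
) -> list[Probe]:
    """Tile 50-mer probes across each exon, alternating strand.

    Probe starts within an exon are evenly spaced at ``step`` bp; exons too
    short for ``min_probes_per_exon`` probes at that step are tiled denser
    (the step is recomputed), and exons shorter than the probe extend
    symmetrically into flanking sequence.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    probes: list[Probe] = []
    for t in targets:
        if t.length >= probe_length:
            win_lo, win_hi = t.start, t.end - probe_length
        else:
            # every probe must contain the whole exon, extending into flanks
            win_lo = t.end - probe_length
            win_hi = t.start
        if win_lo < 0 or (reference_length is not None and win_hi + probe_length > reference_length):
            raise ValueError(
                f"exon {t.chrom}:{t.start}-{t.end} too close to the reference "
                f"edge to tile {probe_length}-mers"
            )
        width = win_hi - win_lo
        natural = width // step + 1
        n = max(natural, min_probes_per_exon)
        if n == 1:
            starts = [win_lo]
        elif n == natural:
            starts = [win_lo + i * step for i in range(n)]
        else:  # densify: even spacing across the window
            starts = [win_lo + round(i * width / (n - 1)) for i in range(n)]
        for i, s in enumerate(starts):
            probes.append(Probe(t.chrom, int(s), probe_length, "+" if i % 2 == 0 else "-"))
    return probes


def plant_variants(
    reference: SimulatedReference,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    off_target_snp_fraction: float = 0.0,
) -> GroundTruth:
    """Plant germline SNPs in targets and convert some het sites to tumor LOH.

    Sites are drawn uniformly (without replacement) over target bases; each
    is heterozygous ref/alt with probability ``het_fraction``, else
    homozygous alt. Each het site becomes an LOH event with probability
    ``loh_fraction``: the tumor keeps one of the two germline alleles,
    chosen uniformly. An optional share of sites is planted off-target.
    """
    if config.snp_density <= 0:
        raise ConfigurationError("snp_density must be > 0")
    if rng is None:
        rng = config.rng()
    index = TargetIndex(reference.targets)
    mask = index.mask(reference.chrom, len(reference.sequence))
    target_pos = np.flatnonzero(mask)
    off_pos = np.flatnonzero(~mask)

    n_sites = int(round(config.snp_density * len(target_pos) / 1000.0))
    n_off = int(round(n_sites * off_target_snp_fraction))
    chosen = rng.choice(target_pos, size=min(n_sites, len(target_pos)), replace=False)
    if n_off:
        chosen = np.concatenate([chosen, rng.choice(off_pos, size=n_off, replace=False)])
    chosen = np.sort(chosen)

    truth = GroundTruth()
    seq = reference.sequence
    for pos in chosen.tolist():
        ref = seq[pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        het = rng.random() < config.het_fraction
        germ = tuple(sorted((ref, alt))) if het else (alt, alt)
        truth.ref_alleles[pos] = ref
        truth.germline_genotypes[pos] = germ
        if het and rng.random() < config.loh_fraction:
            kept = germ[int(rng.integers(0, 2))]
            truth.tumor_genotypes[pos] = (kept, kept)
            truth.loh_events.add(pos)
        else:
            truth.tumor_genotypes[pos] = germ
    return truth


def simulate_reads(
    reference: SimulatedReference,
    truth: GroundTruth,
    config: SimConfig,
    tissue: str = "normal",
    sample_id: str | None = None,
    rng: np.random.Generator | None = None,
):
    """Draw FR read pairs from diploid fragments; returns list of read tuples.

    Each fragment has an outer length uniform in ``insert_range``; read 1 is
    the fragment's first ``read_length`` bases (forward strand), read 2 the
    reverse complement of its last ``read_length`` bases. Fragments start
    inside a target region except for an ``off_target_fraction`` share drawn
    from off-target space. At each planted site covered by a fragment one of
    the two alleles of the tissue's genotype is chosen uniformly (no phasing).
    Per-base substitution errors occur at ``error_rate``; with probability
    ``n_artifact_rate`` a read receives 3 N substitutions. Origins are
    recorded in ``truth.read_origin``.

    Returns ``[(read_id, seq1, seq2), ...]``.
    """
    if config.n_read_pairs < 1:
        raise ConfigurationError("n_read_pairs must be >= 1")
    if config.insert_range[1] > len(reference.sequence):
        raise ConfigurationError("fragment longer than reference")
    if rng is None:
        rng = config.rng()
    sample_id = sample_id or tissue
    genotypes = truth.genotypes(tissue)
    var_pos = np.array(sorted(genotypes), dtype=np.int64)
    var_geno = [genotypes[p] for p in var_pos.tolist()]

    index = TargetIndex(reference.targets)
    mask = index.mask(reference.chrom, len(reference.sequence))
    L = len(reference.sequence)
    ins_lo, ins_hi = config.insert_range
    # fragment starts must leave room for the longest possible fragment
    valid = np.flatnonzero(mask[: L - ins_hi])
    off_valid = np.flatnonzero(~mask[: L - ins_hi])

    n = config.n_read_pairs
    off_flags = rng.random(n) < config.off_target_fraction
    starts = np.empty(n, dtype=np.int64)
    n_off = int(off_flags.sum())
    if n - n_off and len(valid) == 0:
        raise ConfigurationError("no on-target fragment start positions")
    if n_off and len(off_valid) == 0:
        raise ConfigurationError("no off-target fragment start positions")
    if n - n_off:
        starts[~off_flags] = rng.choice(valid, size=n - n_off, replace=True)
    if n_off:
        starts[off_flags] = rng.choice(off_valid, size=n_off, replace=True)
    inserts = rng.integers(ins_lo, ins_hi + 1, size=n)

    rl = config.read_length
    reads: list[tuple[str, str, str]] = []
    seq = reference.sequence
    for i in range(n):
        start = int(starts[i])
        insert = int(inserts[i])
        end = start + insert
        frag = list(seq[start:end])
        lo = int(np.searchsorted(var_pos, start, side="left"))
        hi = int(np.searchsorted(var_pos, end, side="left"))
        for j in range(lo, hi):
            pair = var_geno[j]
            allele = pair[int(rng.integers(0, 2))] if pair[0] != pair[1] else pair[0]
            frag[int(var_pos[j]) - start] = allele
        r1 = "".join(frag[:rl])
        r2 = revcomp("".join(frag[-rl:]))
        if config.error_rate > 0:
            r1 = _add_errors(r1, config.error_rate, rng)
            r2 = _add_errors(r2, config.error_rate, rng)
        if config.n_artifact_rate > 0:
            if rng.random() < config.n_artifact_rate:
                r1 = _add_ns(r1, rng)
            if rng.random() < config.n_artifact_rate:
                r2 = _add_ns(r2, rng)
        rid = f"{sample_id}:{i}"
        truth.read_origin[rid] = (start, not bool(off_flags[i]))
        reads.append((rid, r1, r2))
    return reads


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    hits = np.flatnonzero(rng.random(len(read)) < rate)
    if len(hits) == 0:
        return read
    out = list(read)
    for p in hits.tolist():
        out[p] = str(rng.choice([b for b in "ACGT" if b != out[p]]))
    return "".join(out)


def _add_ns(read: str, rng: np.random.Generator, n: int = 3) -> str:
    out = list(read)
    for p in rng.choice(len(read), size=n, replace=False).tolist():
        out[p] = "N"
    return "".join(out)


# ---------------------------------------------------------------------------
# file output


def write_fasta(reference: SimulatedReference, path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(reference.sequence), id=reference.chrom, description="")],
        str(path),
        "fasta",
    )


def write_fastq(reads, path1: str | Path, path2: str | Path, quality: str = "I") -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rid, r1, r2 in reads:
            f1.write(f"@{rid}/1\n{r1}\n+\n{quality * len(r1)}\n")
            f2.write(f"@{rid}/2\n{r2}\n+\n{quality * len(r2)}\n")


def write_probes_bed(probes: Sequence[Probe], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(probes):
            fh.write(f"{p.chrom}\t{p.start}\t{p.start + p.length}\tprobe{i + 1}\t0\t{p.strand}\n")


def write_truth_tsv(truth: GroundTruth, path: str | Path) -> None:
    """Ground truth as TSV: 1-based position, ref, genotypes, LOH flag."""
    with open(path, "w") as fh:
        fh.write("pos\tref\tnormal_genotype\ttumor_genotype\tloh\n")
        for pos in sorted(truth.germline_genotypes):
            g = "".join(truth.germline_genotypes[pos])
            t = "".join(truth.tumor_genotypes[pos])
            fh.write(f"{pos + 1}\t{truth.ref_alleles[pos]}\t{g}\t{t}\t"
                     f"{int(pos in truth.loh_events)}\n")


def simulate_patient(
    reference: SimulatedReference,
    config: SimConfig,
    patient: str,
    variant_seed: int,
    read_seed_normal: int,
    read_seed_tumor: int,
):
    """Plant one patient's variants and draw reads for both tissues.

    Returns (truth, normal_reads, tumor_reads). Seeds are explicit so the
    two patients of a cohort are independent but individually reproducible.
    """
    truth = plant_variants(reference, config, rng=np.random.default_rng(variant_seed))
    normal = simulate_reads(reference, truth, config, "normal",
                            sample_id=f"{patient}-leuko",
                            rng=np.random.default_rng(read_seed_normal))
    tumor = simulate_reads(reference, truth, config, "tumor",
                           sample_id=f"{patient}-tumor",
                           rng=np.random.default_rng(read_seed_tumor))
    return truth, normal, tumor
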