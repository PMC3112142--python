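"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results the simplest possible way
(all-offsets Hamming scans, per-element set membership, per-base recounts)
so the package's optimised paths are checked against them.
"""

from __future__ import annotations

import numpy as np
import pytest

from capture_snp.mapping import encode_read, encode_reference
from capture_snp.simulate import SimConfig, revcomp


# ---------------------------------------------------------------------------
# oracles


def brute_force_map(seq: str, reference: str, max_mm: int = 3):
    """All-offsets, both-strand Hamming scan; the mapping oracle.

    Returns (status, strand, pos, mismatches) with the same uniqueness
    semantics as the mapper: a tie at the minimal distance means 'multi'.
    """
    L = len(seq)
    if L > len(reference):
        return ("unmapped", ".", -1, 0)
    ref = encode_reference(reference)
    placements = []
    for strand, q in (("+", encode_read(seq)), ("-", encode_read(revcomp(seq)))):
        for pos in range(len(reference) - L + 1):
            mm = int((ref[pos:pos + L] != q).sum())
            if mm <= max_mm:
                placements.append((mm, strand, pos))
    if not placements:
        return ("unmapped", ".", -1, 0)
    placements.sort(key=lambda t: (t[0], t[1], t[2]))
    best = placements[0][0]
    if sum(1 for m, *_ in placements if m == best) > 1:
        return ("multi", ".", -1, best)
    m, s, p = placements[0]
    return ("unique", s, p, m)


def brute_force_depth(alignments, reference_length: int, target_mask):
    """Per-base recount of depth: iterate every base of every read span."""
    depth = np.zeros(reference_length, dtype=int)
    for a in alignments:
        for p in range(a.pos, a.end):
            depth[p] += 1
    depth[~target_mask] = 0
    return depth


def brute_force_partition(a, b):
    """Per-element membership scan partition of two key sets."""
    only_a = sum(1 for x in set(a) if x not in set(b))
    only_b = sum(1 for x in set(b) if x not in set(a))
    both = sum(1 for x in set(a) if x in set(b))
    return only_a, only_b, both


# ---------------------------------------------------------------------------
# simulation fixtures


def small_config(**overrides) -> SimConfig:
    base = dict(
        reference_length=60_000,
        n_genes=6,
        exons_per_gene=6,
        exon_length_range=(120, 500),
        target_fraction=0.2,
        snp_density=3.0,
        loh_fraction=0.0,
        n_read_pairs=5_000,
        error_rate=0.0,
        n_artifact_rate=0.0,
        off_target_fraction=0.2,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def clean_experiment():
    """Small error-free, decoy-free experiment: reference + truth + reads."""
    from capture_snp.simulate import generate_reference, plant_variants, simulate_reads

    cfg = small_config()
    ref = generate_reference(cfg)
    truth = plant_variants(ref, cfg, rng=np.random.default_rng(101))
    reads = simulate_reads(ref, truth, cfg, "normal", "n",
                           rng=np.random.default_rng(102))
    return cfg, ref, truth, reads


@pytest.fixture(scope="session")
def recovery_experiment():
    """Deep simulation for parameter-recovery checks.

    ~690 planted sites over ~115 kb of targets, planted-site depth ~120 on
    average, 1% sequencing error, 10% of het sites converted to tumor LOH;
    both tissues are simulated, mapped, paired and called.
    """
    from capture_snp import calling, mapping
    from capture_snp.simulate import generate_reference, plant_variants, simulate_reads

    cfg = SimConfig(
        reference_length=480_000,
        n_genes=40,
        exons_per_gene=8,
        exon_length_range=(120, 600),
        target_fraction=0.24,
        snp_density=6.0,
        het_fraction=0.6,
        loh_fraction=0.1,
        n_read_pairs=300_000,
        error_rate=0.01,
        n_artifact_rate=0.01,
        off_target_fraction=0.3,
        seed=2024,
    )
    ref = generate_reference(cfg)
    truth = plant_variants(ref, cfg, rng=np.random.default_rng(7001))
    index = mapping.ReferenceIndex(ref.sequence, ref.chrom)

    calls = {}
    for tissue, read_seed in (("normal", 7002), ("tumor", 7003)):
        reads = simulate_reads(ref, truth, cfg, tissue, tissue,
                               rng=np.random.default_rng(read_seed))
        pairs = [mapping.ReadPair(rid, r1, r2) for rid, r1, r2 in reads]
        kept, _ = mapping.filter_ambiguous(pairs)
        aln1 = mapping.map_reads([p.seq1 for p in kept], index)
        aln2 = mapping.map_reads([p.seq2 for p in kept], index)
        accepted, _ = mapping.accept_pairs(aln1, aln2)
        columns = calling.build_pileup(accepted, ref.sequence, ref.targets, ref.chrom)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", calling.TriallelicWarning)
            calls[tissue] = {c.pos - 1: calling.call_genotype(c) for c in columns}
    return cfg, ref, truth, calls
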