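# Methods

## The analysis model

The pipeline reconstructs a capture-resequencing SNP analysis as a chain
of explicit, individually testable rules rather than as wrappers around
the original (partly commercial, partly unavailable) tool chain.

**Mapping.** A read maps at an offset if the ungapped Hamming distance to
the reference is ≤ 3, with N in the read mismatching every reference base
and N in the reference matching nothing. The mapper enumerates *all* such
placements on both strands. Uniqueness uses best-stratum semantics: a
read is unique only when exactly one placement attains the minimal
distance; any tie makes it multi-mapped and it is excluded from depth,
pileups and calls. A `strict` flag instead treats any second placement
within the budget as multi. For speed, four disjoint 12 bp segments of
the read are looked up in a k-mer index; by pigeonhole, any placement
with ≤ 3 mismatches matches at least one segment exactly, so verifying
every seed hit with a full Hamming comparison is exhaustive-equivalent.
This equivalence is enforced by a property test against a literal
all-offsets scan on references up to 2 kb. Reads shorter than four seed
lengths fall back to the literal scan.

**Pair acceptance.** The fragment ("insert") is the *outer* span — from
the forward-strand mate's first base to the reverse-strand mate's last
base, inclusive. This is the only reading under which a 100–500 bp window
is compatible with two 50 bp reads, and the simulator and the filter
share it. Bounds are inclusive. Orientation must be FR/inward (the
forward-strand mate leftmost), the standard geometry of the sequencing
platform being emulated. The N-filter removes whole pairs when either
mate has ≥ 3 N because all downstream logic is pair-based.

**Coverage.** Depth is defined on target bases only; read spans are
clipped to targets. The headline mean fold is
`read_count × read_length / target_bases` — the definition that
reproduces the published headline (3.1×10⁶ reads × 50 bp / 504 kb →
308-fold) — with the mean of per-base depths exported alongside, since
the two differ whenever reads extend beyond target edges. The
covered-fraction threshold defaults to depth ≥ 1 (no threshold is stated
for the published 87 % figure). Enrichment fold is the observed on-target
read fraction divided by `target_size / genome_size`.

**Genotype calling.** Pileup columns carry per-base counts split by
alignment strand. Calling ranks alleles by total count; with
`minor_fraction = second_count / depth`, a site is het iff
`minor_fraction ≥ het_min_fraction`. The published call table dictates
the window for this threshold: the largest minor fraction called
homozygous is 0.172 and the smallest called heterozygous 0.254, so the
default 0.20 sits inside (0.172, 0.254) and reproduces all 14 published
genotypes; a calibration test pins both ends of that window. Calling is
symmetric in the two strand counts (the published "x;y" order is never
stated, and a test asserts strand swaps change nothing), and there is
deliberately no strand-balance filter — one published het has all of its
minor-allele support on a single strand. Columns with more than two
alleles are called from the top two with a warning. Confidence tiers read
the published wording literally: depth < 10 removed, depth > 50 high,
the inclusive band 10–50 low. Two published rows have printed coverages
that exceed their count sums by one read; the package computes depth from
counts and the fixture records both numbers.

**Tumor–normal comparison.** Candidates require confident calls in both
tissues (default depth > 50 in both, configurable) and differing allele
sets. Normal-het → tumor-hom-of-a-contained-allele is classified
`loh_or_hom`; read counts cannot distinguish loss of heterozygosity from
hemizygosity, so the class name never claims a somatic mutation. Any
other difference is `other_diff`.

**Set statistics and annotation.** Variant identity is the allele-aware
key (chrom, pos, alt); the known/novel split requires allele matching,
with a position-only mode available since the original matching
granularity is unstated. Pairwise overlap uses the union denominator,
which reproduces all six published percentages exactly (verified in the
suite); percentages are rounded half-up to one decimal. Haplotype
encoding emits '1' for homozygous-minor and '0' for homozygous-major per
site and refuses to phase: any het site returns "unphased".

## The simulator and what it does (not) model

`SimConfig` defaults define the study conditions at a single-machine
scale: a 0.5 Mb reference with 40 genes × 8 exons (120–600 bp), 23 % of
the reference in targets (the 504 kb core / 2.2 Mb design-region ratio),
2.6 SNPs per target kb (≈ the 1317 SNPs / 504 kb of the original panel),
60 % of planted sites heterozygous, 5 % of het sites converted to tumor
LOH with the retained allele chosen uniformly, 50 bp reads, 100–500 bp
outer fragments, 0.5 % per-base error, 2 % N-artifact reads, 30 %
off-target pairs. Genotypes are unordered allele pairs; fragments pick
one allele per covered site uniformly (no phasing, as none is used
downstream). Probe tiling follows the published design rules (50-mers,
11 bp step, alternating strands, ≥ 20 probes per exon with denser tiling
of small exons and symmetric flanks for sub-probe exons); the published
probe total is numerically inconsistent with its own stated density and
is not reproduced. Decoy duplications copy target segments into
off-target space so that reads from them become genuine multi-mappers.

Not modelled: indels, structural variants, CNV, GC or mappability bias,
base-quality decay, PCR duplicates, machine-specific error profiles.
Passing recovery tests therefore demonstrate correctness of the analysis
logic under idealized error processes, not caller performance on real
tumor genomes.

All randomness flows through one seeded generator per stage with a fixed
draw order (reference, geometry, decoys, variants, reads), giving
byte-identical FASTA/BED/FASTQ/outputs per seed; cohort runs derive
per-patient, per-tissue child seeds from the master seed.

## Problem sizes used in the checks

The recovery experiments run at a scale chosen to give ≥ 500 deeply
covered planted sites while staying comfortably single-CPU: 480 kb
reference, 115 kb of targets, 6 planted SNPs per target kb (~690 sites —
density raised above the default because per-site recovery is independent
of density and this reaches the required site count at 300 000 read pairs
per tissue, ~120× mean planted-site depth), 1 % error. Genotype recovery
is evaluated at sites with depth ≥ 50 in the leukocyte sample; LOH
recovery at planted LOH sites with depth > 50 in both tissues. The
null-cohort false-candidate check and the determinism check use a smaller
error-free configuration (60–80 kb reference, 4 000–5 000 pairs).

## Numerical and degenerate-input choices

Half-up decimal rounding for all table-style percentages (Python's
banker's rounding would print 19.45 → 19.4). Zero-depth columns are
no-calls (raise), empty target sets and empty cohorts are errors, a read
longer than the reference is unmapped rather than an error, and a
SimConfig whose exon geometry cannot achieve the requested target
fraction within ±10 % relative fails validation before any work.
Allele-rank ties in calling break alphabetically (deterministic; affects
only exact 50/50 columns). Triallelic warnings are aggregated to one log
line per sample in pipeline runs.

## Known limitations

The caller is a calibrated reconstruction of the original commercial
caller's observable behaviour, not its (unknown) internal model; it has
no genotype likelihoods or base-quality awareness. The mapper is
single-contig-index, ungapped and fixed-budget by design — reads crossing
real indels would simply fail to map. Published genome-wide totals
(per-sample SNP counts, the four-way Venn, the 87 % covered fraction and
the 844-fold enrichment) depend on the original patient data and are out
of reach of a simulation; the suite instead validates the printed
desk-reproducible quantities exactly and the pipeline's recovery behaviour
on ground-truthed synthetic data.
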