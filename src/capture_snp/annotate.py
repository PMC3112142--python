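"""Tumor-normal comparison, SNP-set overlap statistics and annotation.

Covers genotype-difference (LOH-candidate) detection between matched
leukocyte and tumor samples, pairwise/Venn set statistics over
allele-aware variant keys, matching against known-SNP and GWAS-catalog
tables, gene-level summaries, binary minor/major-allele haplotype
encoding, and cohort genotype frequencies.

A tumor homozygous for one of the normal's two alleles cannot be
distinguished from hemizygosity using read counts alone, so that class is
named ``loh_or_hom``, never a somatic mutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calling import GenotypeCall, VariantRecord
from .coverage import round_half_up


@dataclass
class LohCandidate:
    """A position where one patient's leukocyte and tumor genotypes differ."""

    patient: str
    chrom: str
    pos: int  # 1-based
    gene: str
    normal_genotype: tuple[str, str]
    tumor_genotype: tuple[str, str]
    interpretation: str  # loh_or_hom | other_diff
    normal_depth: int = 0
    tumor_depth: int = 0


@dataclass
class OverlapStats:
    only_a: int
    only_b: int
    both: int

    @property
    def union(self) -> int:
        return self.only_a + self.only_b + self.both

    @property
    def percent(self) -> float:
        """Overlap as percent of the union, half-up to one decimal."""
        if self.union == 0:
            return 0.0
        return round_half_up(100.0 * self.both / self.union, 1)


@dataclass
class HaplotypeDef:
    """Ordered (rsid, minor allele, major allele) sites of one haplotype."""

    sites: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for rsid, minor, major in self.sites:
            if minor == major:
                raise ValueError(f"{rsid}: minor allele equals major allele")

    @classmethod
    def from_tsv(cls, path: str) -> "HaplotypeDef":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(list(df[["rsid", "minor", "major"]].itertuples(index=False, name=None)))


class AnnotationTable:
    """Known-SNP table keyed by allele-aware (chrom, pos, alt)."""

    def __init__(self, rows: Iterable[tuple]):
        """rows: (rsid, chrom, pos 1-based, ref, alt[, trait/gene])."""
        self.by_key: dict[tuple, tuple[str, str]] = {}
        self.by_pos: dict[tuple, str] = {}
        for row in rows:
            rsid, chrom, pos, ref, alt = row[:5]
            extra = row[5] if len(row) > 5 else ""
            key = (chrom, int(pos), alt)
            if key in self.by_key:
                raise ValueError(f"duplicate annotation key {key}")
            self.by_key[key] = (rsid, extra)
            self.by_pos[(chrom, int(pos))] = rsid

    @classmethod
    def from_tsv(cls, path: str) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        cols = ["rsid", "chrom", "pos", "ref", "alt"]
        extra = [c for c in ("trait", "gene") if c in df.columns]
        return cls(df[cols + extra].itertuples(index=False, name=None))

    def __len__(self) -> int:
        return len(self.by_key)


def compare_tumor_normal(
    normal_calls: Mapping[tuple[str, int], GenotypeCall] | Iterable[GenotypeCall],
    tumor_calls: Mapping[tuple[str, int], GenotypeCall] | Iterable[GenotypeCall],
    patient: str,
    min_depth: int = 51,
    gene_of=None,
) -> list[LohCandidate]:
    """Positions confidently called in both tissues with differing genotypes.

    Both calls must reach ``min_depth`` (default: strictly above 50 reads).
    A candidate is ``loh_or_hom`` when the normal is heterozygous and the
    tumor homozygous for one of the normal's alleles; anything else is
    ``other_diff``.
    """
    normal = _as_map(normal_calls)
    tumor = _as_map(tumor_calls)
    out: list[LohCandidate] = []
    for key in sorted(set(normal) & set(tumor)):
        n, t = normal[key], tumor[key]
        if n.depth < min_depth or t.depth < min_depth:
            continue
        if n.alleles == t.alleles:
            continue
        loh = (n.is_het and t.zygosity != "het"
               and set(t.genotype) <= set(n.genotype))
        gene = gene_of(n.chrom, n.pos) if gene_of else ""
        out.append(LohCandidate(patient, n.chrom, n.pos, gene, n.genotype,
                                t.genotype, "loh_or_hom" if loh else "other_diff",
                                n.depth, t.depth))
    return out


def _as_map(calls) -> dict[tuple[str, int], GenotypeCall]:
    if isinstance(calls, Mapping):
        return dict(calls)
    return {(c.chrom, c.pos): c for c in calls}


def pairwise_overlap(set_a: Iterable, set_b: Iterable) -> OverlapStats:
    """Exact two-set partition of variant keys (only-A / only-B / both)."""
    a, b = set(set_a), set(set_b)
    both = len(a & b)
    return OverlapStats(len(a) - both, len(b) - both, both)


def venn_counts(named_sets: Mapping[str, Iterable]) -> dict[frozenset, int]:
    """Counts per non-empty membership pattern for 2-4 named sets.

    Returns {frozenset of set names: count}; patterns absent from the data
    are reported as 0. The counts over all patterns sum to |union|.
    """
    names = list(named_sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_counts supports 2-4 sets")
    sets = {n: set(v) for n, v in named_sets.items()}
    patterns: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            patterns[frozenset(combo)] = 0
    for element in set().union(*sets.values()):
        member = frozenset(n for n in names if element in sets[n])
        patterns[member] += 1
    return patterns


def annotate_known(
    variants: Sequence[VariantRecord],
    table: AnnotationTable,
    position_only: bool = False,
):
    """Fill rsids from the table; returns (variants, known count, novel count).

    Matching is allele-aware on (chrom, pos, alt) by default; with
    ``position_only`` any variant at a listed position counts as known.
    """
    known = 0
    for v in variants:
        rsid = ""
        if position_only:
            rsid = table.by_pos.get((v.chrom, v.pos), "")
        else:
            for alt in v.alt:
                hit = table.by_key.get((v.chrom, v.pos, alt))
                if hit:
                    rsid = hit[0]
                    break
        if rsid:
            v.rsid = rsid
            known += 1
    return variants, known, len(variants) - known


def gene_summary(
    variants_by_sample: Mapping[str, Sequence[VariantRecord]],
    gene_list: Sequence[str],
):
    """Per-gene SNP presence across samples and percent of genes hit.

    A listed gene is "hit" when any sample carries >=1 variant assigned to
    it. Returns (presence dict, percent with one decimal).
    """
    if not gene_list:
        raise ValueError("empty gene list")
    hit_genes = {v.gene for recs in variants_by_sample.values() for v in recs if v.gene}
    presence = {g: g in hit_genes for g in gene_list}
    percent = round_half_up(100.0 * sum(presence.values()) / len(gene_list), 1)
    return presence, percent


def encode_haplotype(
    calls_by_rsid: Mapping[str, GenotypeCall | tuple[str, str]],
    definition: HaplotypeDef,
) -> str:
    """Binary minor/major haplotype code, e.g. "1100".

    Per site: '1' if homozygous for the minor allele, '0' if homozygous for
    the major allele. Any heterozygous site, or an allele not in the
    definition, returns "unphased" (no phasing is attempted). A site
    missing from the sample raises.
    """
    code = []
    for rsid, minor, major in definition.sites:
        if rsid not in calls_by_rsid:
            raise KeyError(f"no genotype call for haplotype site {rsid}")
        call = calls_by_rsid[rsid]
        genotype = call.genotype if isinstance(call, GenotypeCall) else tuple(call)
        a, b = genotype
        if a != b:
            return "unphased"
        if a == minor:
            code.append("1")
        elif a == major:
            code.append("0")
        else:
            return "unphased"
    return "".join(code)


def cohort_genotype_freq(genotypes: Sequence[str]) -> dict[str, dict[str, float]]:
    """Genotype-class percentages (nearest whole percent) with counts.

    ``genotypes`` entries must be 'hom_major', 'het' or 'hom_minor'.
    Returns {class: {"count": n, "percent": p}}.
    """
    if not genotypes:
        raise ValueError("empty cohort")
    classes = ("hom_major", "het", "hom_minor")
    bad = set(genotypes) - set(classes)
    if bad:
        raise ValueError(f"unknown genotype classes: {sorted(bad)}")
    n = len(genotypes)
    out = {}
    for c in classes:
        count = sum(1 for g in genotypes if g == c)
        out[c] = {"count": count, "percent": round_half_up(100.0 * count / n)}
    return out


# ---------------------------------------------------------------------------
# tabular output


def overlap_table(sets: Mapping[str, Iterable]) -> pd.DataFrame:
    """All pairwise overlaps in the published table layout."""
    rows = []
    for a, b in combinations(sets, 2):
        st = pairwise_overlap(sets[a], sets[b])
        rows.append((a, b, st.only_a, st.only_b, st.both, st.percent))
    return pd.DataFrame(rows, columns=["sample_1", "sample_2", "only_in_sample_1",
                                       "only_in_sample_2", "in_both", "overlap_percent"])


def loh_table(candidates: Sequence[LohCandidate]) -> pd.DataFrame:
    rows = [(c.patient, c.gene, c.pos, c.chrom, "".join(c.normal_genotype),
             c.normal_depth, "".join(c.tumor_genotype), c.tumor_depth,
             c.interpretation) for c in candidates]
    return pd.DataFrame(rows, columns=["patient", "gene", "position", "chromosome",
                                       "leukocyte_genotype", "leukocyte_depth",
                                       "tumor_genotype", "tumor_depth",
                                       "interpretation"])


def venn_table(patterns: Mapping[frozenset, int]) -> pd.DataFrame:
    rows = [("+".join(sorted(k)), v) for k, v in patterns.items()]
    rows.sort(key=lambda r: (r[0].count("+"), r[0]))
    return pd.DataFrame(rows, columns=["samples", "count"])
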