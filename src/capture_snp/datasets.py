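"""Loaders for the small reference tables shipped with the package.

These cover the published validation fixtures: the strand-split pileup
rows of the seven tumor/leukocyte genotype-difference positions, the six
pairwise SNP-set partition counts, a four-site SART1 haplotype definition
(three allele pairs synthetic), and a 21-entry antigen gene list (thirteen
names synthetic).
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .annotate import HaplotypeDef
from .calling import GenotypeCall, PileupColumn, column_from_counts

_DATA = files("capture_snp.data")


def load_tumor_normal_pileups() -> pd.DataFrame:
    """The 14 published strand-split count rows (7 positions x 2 tissues)."""
    return pd.read_csv(_DATA / "tumor_normal_pileups.tsv", sep="\t", comment="#",
                       dtype={"chrom": str})


def tumor_normal_columns():
    """Pileup columns and expected genotypes from the published rows.

    Returns a list of (row metadata dict, PileupColumn, expected genotype
    string, printed coverage).
    """
    out = []
    for _, row in load_tumor_normal_pileups().iterrows():
        col = column_from_counts(
            str(row["chrom"]), int(row["pos"]), row["ref"],
            {b: row[b] for b in "ACGT"},
        )
        meta = {"patient": row["patient"], "gene": row["gene"],
                "sample": row["sample"], "rsid": row["rsid"]}
        out.append((meta, col, row["genotype"], int(row["coverage"])))
    return out


def load_pairwise_overlap_counts() -> pd.DataFrame:
    """The six published pairwise (only-A, only-B, both) partition counts."""
    return pd.read_csv(_DATA / "pairwise_overlap_counts.tsv", sep="\t", comment="#")


def load_sart1_haplotype() -> HaplotypeDef:
    """Four-site SART1 haplotype definition (partly synthetic alleles)."""
    return HaplotypeDef.from_tsv(str(_DATA / "sart1_haplotype_synthetic.tsv"))


def load_antigen_genes() -> list[str]:
    """21-entry antigen gene list (partly synthetic names)."""
    text = (_DATA / "antigen_genes_synthetic.txt").read_text()
    return [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]
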