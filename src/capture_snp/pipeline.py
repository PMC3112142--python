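"""End-to-end orchestration: QC -> map -> pair -> coverage -> call -> compare.

The pipeline consumes a sample sheet of (sample id, patient, tissue)
entries, runs every stage with per-stage input/output counts in the run
log, and writes standard-format artifacts (VCF, BEDGraph, TSV tables,
JSON summary). All stages are deterministic for fixed inputs and
configuration; simulated runs are reproducible from the seed alone.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import annotate, calling, coverage, mapping, simulate
from .regions import TargetRegion, read_bed, write_bed


@dataclass
class SampleSpec:
    sample_id: str
    patient: str
    tissue: str  # leukocyte | tumor

    def __post_init__(self) -> None:
        if self.tissue not in ("leukocyte", "tumor"):
            raise ValueError(f"tissue must be leukocyte or tumor, got {self.tissue!r}")


@dataclass
class PipelineConfig:
    """Paths, thresholds and the sample sheet of one pipeline run."""

    reference: str = ""
    targets: str = ""
    reads: dict[str, tuple[str, str]] = field(default_factory=dict)  # sample -> (fq1, fq2)
    output_dir: str = "capture_snp_out"
    sample_sheet: list[SampleSpec] = field(default_factory=list)
    annotation_table: str = ""  # known-SNP TSV (rsid chrom pos ref alt)
    gene_list: str = ""  # plain-text gene list for the gene summary
    # thresholds
    max_n_per_read: int = 2
    max_mismatches: int = 3
    min_fragment: int = 100
    max_fragment: int = 500
    het_min_fraction: float = 0.20
    drop_below: int = 10
    high_above: int = 50
    compare_min_depth: int = 51
    seed: int = 0

    def validate(self) -> None:
        patients: dict[str, set[str]] = {}
        for s in self.sample_sheet:
            patients.setdefault(s.patient, set()).add(s.tissue)
        for p, tissues in patients.items():
            if tissues != {"leukocyte", "tumor"}:
                raise ValueError(
                    f"patient {p}: sample sheet must pair one leukocyte with one "
                    f"tumor sample (got {sorted(tissues)})")
        for s in self.sample_sheet:
            if s.sample_id not in self.reads:
                raise ValueError(f"no reads configured for sample {s.sample_id}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sheet = [SampleSpec(**s) for s in raw.pop("sample_sheet", [])]
        reads = {k: tuple(v) for k, v in raw.pop("reads", {}).items()}
        return cls(sample_sheet=sheet, reads=reads, **raw)


def _read_fasta(path: str) -> tuple[str, str]:
    from Bio import SeqIO

    rec = next(SeqIO.parse(path, "fasta"))
    return rec.id, str(rec.seq).upper()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the machine-readable summary dict.

    Aborts (removing partial outputs) if any stage fails; the run log
    records input/output counts of every filter so no read is dropped
    silently.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    try:
        chrom, reference = _read_fasta(config.reference)
        targets = read_bed(config.targets)
        index = mapping.ReferenceIndex(reference, chrom)
        gene_of = calling.gene_lookup(targets)

        summary: dict = {"samples": {}, "thresholds": {
            "het_min_fraction": config.het_min_fraction,
            "drop_below": config.drop_below, "high_above": config.high_above,
            "min_fragment": config.min_fragment, "max_fragment": config.max_fragment,
        }}
        calls_by_sample: dict[str, dict] = {}
        variants_by_sample: dict[str, list] = {}

        for spec in config.sample_sheet:
            sid = spec.sample_id
            fq1, fq2 = config.reads[sid]
            pairs = mapping.read_fastq_pairs(fq1, fq2)
            n_in = len(pairs)
            kept, n_removed = mapping.filter_ambiguous(pairs, config.max_n_per_read)
            log(f"[{sid}] qc: pairs_in={n_in} kept={len(kept)} removed_n_filter={n_removed}")
            assert n_in == len(kept) + n_removed

            aln1 = mapping.map_reads([p.seq1 for p in kept], index,
                                     [p.id + "/1" for p in kept], config.max_mismatches)
            aln2 = mapping.map_reads([p.seq2 for p in kept], index,
                                     [p.id + "/2" for p in kept], config.max_mismatches)
            stat = {"unique": 0, "multi": 0, "unmapped": 0}
            for a in aln1 + aln2:
                stat[a.status] += 1
            log(f"[{sid}] map: reads={2 * len(kept)} unique={stat['unique']} "
                f"multi={stat['multi']} unmapped={stat['unmapped']}")

            accepted, reasons = mapping.accept_pairs(
                aln1, aln2, config.min_fragment, config.max_fragment)
            log(f"[{sid}] pair: pairs_in={len(kept)} accepted={len(accepted)} "
                + " ".join(f"{k}={v}" for k, v in reasons.items()))
            assert len(kept) == len(accepted) + sum(reasons.values())

            track = coverage.compute_depth(accepted, targets, len(reference), chrom)
            on_reads, total_reads = coverage.count_on_target(accepted, targets)
            summ = coverage.summarize_coverage(track, targets, on_reads,
                                               kept[0].seq1.__len__() if kept else 50,
                                               total_mapped_reads=total_reads)
            enr = (coverage.enrichment_fold(on_reads, total_reads,
                                            sum(t.length for t in targets),
                                            len(reference))
                   if total_reads else 0.0)
            coverage.write_bedgraph(track, str(out / f"{sid}.depth.bedgraph"))
            log(f"[{sid}] coverage: mean_fold={summ.mean_fold_rounded} "
                f"fraction_covered={summ.fraction_covered:.4f} enrichment={enr:.1f}")

            columns = calling.build_pileup(accepted, reference, targets, chrom)
            import warnings as _warnings

            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always", calling.TriallelicWarning)
                calls = [calling.call_genotype(c, config.het_min_fraction)
                         for c in columns]
            n_tri = sum(1 for w in caught
                        if issubclass(w.category, calling.TriallelicWarning))
            if n_tri:
                log(f"[{sid}] call: {n_tri} columns with >2 alleles "
                    "(called from top two)")
            kept_calls, n_depth_removed = calling.confidence_filter(
                calls, config.drop_below, config.high_above)
            log(f"[{sid}] call: columns={len(columns)} calls={len(calls)} "
                f"kept={len(kept_calls)} removed_low_depth={n_depth_removed}")
            variants = calling.emit_variants(kept_calls, sid, gene_of)
            calling.write_vcf(variants, str(out / f"{sid}.vcf"),
                              {chrom: len(reference)}, sid)
            calls_by_sample[sid] = {(c.chrom, c.pos): c for c in kept_calls}
            variants_by_sample[sid] = variants

            summary["samples"][sid] = {
                "pairs_in": n_in, "pairs_after_qc": len(kept),
                "pairs_removed_n_filter": n_removed,
                "reads_unique": stat["unique"], "reads_multi": stat["multi"],
                "reads_unmapped": stat["unmapped"],
                "pairs_accepted": len(accepted), "pair_rejections": reasons,
                "mean_fold": summ.mean_fold_rounded,
                "fraction_covered": summ.fraction_covered,
                "enrichment_fold": enr,
                "n_variants": len(variants),
            }

        # known/novel annotation
        if config.annotation_table:
            table = annotate.AnnotationTable.from_tsv(config.annotation_table)
            for sid, variants in variants_by_sample.items():
                _, known, novel = annotate.annotate_known(variants, table)
                summary["samples"][sid]["known"] = known
                summary["samples"][sid]["novel"] = novel
                log(f"[{sid}] annotate: known={known} novel={novel}")

        # set statistics over allele-aware keys
        keysets = {sid: {v.key for v in recs} for sid, recs in variants_by_sample.items()}
        if len(keysets) >= 2:
            ov = annotate.overlap_table(keysets)
            ov.to_csv(out / "overlap.tsv", sep="\t", index=False)
            summary["overlaps"] = ov.to_dict("records")
        if 2 <= len(keysets) <= 4:
            venn = annotate.venn_counts(keysets)
            annotate.venn_table(venn).to_csv(out / "venn.tsv", sep="\t", index=False)
            summary["venn_all_samples"] = venn[frozenset(keysets)]

        # tumor-normal comparison per patient
        candidates: list[annotate.LohCandidate] = []
        by_patient: dict[str, dict[str, str]] = {}
        for spec in config.sample_sheet:
            by_patient.setdefault(spec.patient, {})[spec.tissue] = spec.sample_id
        for patient, tissues in sorted(by_patient.items()):
            cands = annotate.compare_tumor_normal(
                calls_by_sample[tissues["leukocyte"]],
                calls_by_sample[tissues["tumor"]],
                patient, config.compare_min_depth, gene_of)
            log(f"[{patient}] compare: candidates={len(cands)}")
            candidates.extend(cands)
        annotate.loh_table(candidates).to_csv(out / "loh_candidates.tsv",
                                              sep="\t", index=False)
        summary["n_loh_candidates"] = len(candidates)

        # per-gene summary
        if config.gene_list:
            genes = [l.strip() for l in open(config.gene_list)
                     if l.strip() and not l.startswith("#")]
            presence, percent = annotate.gene_summary(variants_by_sample, genes)
            summary["gene_summary_percent"] = percent
            log(f"gene_summary: {sum(presence.values())}/{len(genes)} genes "
                f"with >=1 SNP ({percent}%)")

        # Table-1 style per-sample totals
        rows = []
        for sid, recs in variants_by_sample.items():
            in_target = [v for v in recs if v.gene]
            rows.append({
                "sample": sid,
                "overall_snps": len(recs),
                "overall_known": sum(1 for v in recs if v.rsid),
                "target_gene_snps": len(in_target),
                "target_gene_known": sum(1 for v in in_target if v.rsid),
            })
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "snp_totals.tsv", sep="\t", index=False)
        summary["snp_totals"] = rows

        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except Exception:
        # remove partial outputs so a failed run leaves no half-written state
        for p in out.glob("*"):
            if p.is_file():
                p.unlink()
        raise


def simulate_cohort(config: simulate.SimConfig, output_dir: str) -> PipelineConfig:
    """Simulate a two-patient tumor/leukocyte cohort and write all inputs.

    Produces reference FASTA, targets/probes BED, per-sample paired FASTQ,
    per-patient ground-truth TSVs, and returns a ready PipelineConfig.
    Per-patient seeds are derived from ``config.seed`` deterministically.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = simulate.generate_reference(config)
    simulate.write_fasta(ref, out / "reference.fasta")
    write_bed(ref.targets, str(out / "targets.bed"))
    probes = simulate.design_probes(ref.targets, reference_length=len(ref.sequence))
    simulate.write_probes_bed(probes, out / "probes.bed")

    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(6)
    reads_cfg: dict[str, tuple[str, str]] = {}
    sheet: list[SampleSpec] = []
    truths = {}
    for pi, patient in enumerate(("patientA", "patientB")):
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in child[pi * 3:pi * 3 + 3]]
        truth, normal_reads, tumor_reads = simulate.simulate_patient(
            ref, config, patient, *seeds)
        simulate.write_truth_tsv(truth, out / f"{patient}.truth.tsv")
        truths[patient] = truth
        for tissue, reads in (("leukocyte", normal_reads), ("tumor", tumor_reads)):
            sid = f"{patient}-{'leuko' if tissue == 'leukocyte' else 'tumor'}"
            fq1 = str(out / f"{sid}_1.fastq")
            fq2 = str(out / f"{sid}_2.fastq")
            simulate.write_fastq(reads, fq1, fq2)
            reads_cfg[sid] = (fq1, fq2)
            sheet.append(SampleSpec(sid, patient, tissue))

    cfg = PipelineConfig(
        reference=str(out / "reference.fasta"),
        targets=str(out / "targets.bed"),
        reads=reads_cfg,
        output_dir=str(out / "results"),
        sample_sheet=sheet,
        seed=config.seed,
    )
    cfg._truths = truths  # type: ignore[attr-defined]  # kept for in-process use
    return cfg
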