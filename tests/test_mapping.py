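"""Read QC, ungapped mapping and pair acceptance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capture_snp.mapping import (
    Alignment,
    AcceptedPair,
    ReadPair,
    ReferenceIndex,
    accept_pairs,
    filter_ambiguous,
    map_read,
    map_reads,
    pair_filter,
    read_sam,
)
from capture_snp.simulate import revcomp

from conftest import brute_force_map


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestFilterAmbiguous:
    @pytest.mark.parametrize(
        "seq1, seq2, kept",
        [
            ("ACGTNNNACGT", "ACGTACGTACG", False),  # 3 N in mate 1
            ("ACGTACGTACG", "ACGTACGTACG", True),  # N-free
            ("ACGTNNGTACG", "ACGTACGTACG", True),  # exactly 2 N: boundary kept
            ("ACGTACGTACG", "NNNNACGTACG", False),  # mate 2 fails -> pair dropped
        ],
    )
    def test_pair_level_n_filter(self, seq1, seq2, kept):
        out, removed = filter_ambiguous([ReadPair("r", seq1, seq2)])
        assert (len(out) == 1) is kept
        assert removed == (0 if kept else 1)

    def test_counts_conserve(self):
        rng = np.random.default_rng(0)
        pairs = []
        for i in range(50):
            s1 = _random_seq(rng, 30)
            if i % 3 == 0:
                s1 = "NNN" + s1[3:]
            pairs.append(ReadPair(str(i), s1, _random_seq(rng, 30)))
        kept, removed = filter_ambiguous(pairs)
        assert len(kept) + removed == 50

    def test_malformed_read_rejected_at_construction(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            ReadPair("bad", "ACGU", "ACGT")


class TestMapRead:
    def test_exact_unique_placement(self):
        rng = np.random.default_rng(1)
        ref = _random_seq(rng, 1000)
        index = ReferenceIndex(ref)
        a = map_read(ref[200:250], index)
        assert (a.status, a.pos, a.strand, a.mismatches) == ("unique", 200, "+", 0)

    def test_reverse_strand_placement(self):
        rng = np.random.default_rng(2)
        ref = _random_seq(rng, 1000)
        index = ReferenceIndex(ref)
        a = map_read(revcomp(ref[300:350]), index)
        assert (a.status, a.pos, a.strand) == ("unique", 300, "-")

    def test_four_substitutions_unmapped(self):
        rng = np.random.default_rng(3)
        ref = _random_seq(rng, 1000)
        index = ReferenceIndex(ref)
        read = list(ref[100:150])
        for i in (5, 15, 25, 35):
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        a = map_read("".join(read), index)
        assert a.status == "unmapped"

    def test_three_substitutions_still_mapped(self):
        rng = np.random.default_rng(3)
        ref = _random_seq(rng, 1000)
        index = ReferenceIndex(ref)
        read = list(ref[100:150])
        for i in (5, 15, 25):
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        a = map_read("".join(read), index)
        assert (a.status, a.pos, a.mismatches) == ("unique", 100, 3)

    def test_duplicated_segment_is_multi(self):
        rng = np.random.default_rng(4)
        core = _random_seq(rng, 400)
        ref = core + _random_seq(rng, 200) + core[50:150] + _random_seq(rng, 100)
        index = ReferenceIndex(ref)
        a = map_read(ref[60:110], index)
        assert a.status == "multi"

    def test_n_counts_as_mismatch(self):
        rng = np.random.default_rng(5)
        ref = _random_seq(rng, 500)
        index = ReferenceIndex(ref)
        read = "NNN" + ref[103:150]
        a = map_read(read, index)
        assert (a.status, a.pos, a.mismatches) == ("unique", 100, 3)
        read4 = "NNNN" + ref[104:150]
        assert map_read(read4, index).status == "unmapped"

    def test_read_longer_than_reference_unmapped(self):
        index = ReferenceIndex("ACGTACGTAC")
        assert map_read("A" * 50, index).status == "unmapped"

    def test_batch_equals_single(self):
        rng = np.random.default_rng(6)
        ref = _random_seq(rng, 2000)
        index = ReferenceIndex(ref)
        reads = [ref[i * 37:i * 37 + 50] for i in range(30)]
        batch = map_reads(reads, index)
        singles = [map_read(r, index) for r in reads]
        for b, s in zip(batch, singles):
            assert (b.status, b.pos, b.strand, b.mismatches) == (
                s.status, s.pos, s.strand, s.mismatches)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_equivalence_with_brute_force_scan(self, seed):
        """Seeded mapper == all-offsets Hamming scan, on reads of all kinds."""
        rng = np.random.default_rng(seed)
        ref = _random_seq(rng, int(rng.integers(200, 2000)))
        index = ReferenceIndex(ref)
        kind = rng.integers(0, 4)
        if kind == 0:  # clean substring
            p = int(rng.integers(0, len(ref) - 50))
            read = ref[p:p + 50]
        elif kind == 1:  # mutated substring
            p = int(rng.integers(0, len(ref) - 50))
            read = list(ref[p:p + 50])
            for i in rng.choice(50, size=int(rng.integers(0, 6)), replace=False):
                read[i] = "ACGTN"[int(rng.integers(0, 5))]
            read = "".join(read)
        elif kind == 2:  # reverse strand
            p = int(rng.integers(0, len(ref) - 50))
            read = revcomp(ref[p:p + 50])
        else:  # random 50-mer
            read = _random_seq(rng, 50)
        got = map_read(read, index)
        status, strand, pos, mm = brute_force_map(read, ref)
        assert got.status == status
        if status == "unique":
            assert (got.strand, got.pos, got.mismatches) == (strand, pos, mm)


class TestPairFilter:
    def _aln(self, pos, strand, status="unique", length=50):
        return Alignment("r", "chr1", pos, strand, 0, status, length)

    def test_accepted_fragment_length(self):
        res = pair_filter(self._aln(1000, "+"), self._aln(1250, "-"))
        assert isinstance(res, AcceptedPair)
        assert res.fragment_length == 300

    @pytest.mark.parametrize(
        "a1, a2, reason",
        [
            ((1000, "+"), (1550, "-"), "too_long"),  # outer length 600
            ((1000, "+"), (1020, "-"), "too_short"),  # outer length 70
            ((1000, "+"), (1200, "+"), "same_strand"),
            ((1200, "+"), (1000, "-"), "outward"),
        ],
    )
    def test_rejection_reasons(self, a1, a2, reason):
        assert pair_filter(self._aln(*a1), self._aln(*a2)) == reason

    def test_inclusive_boundaries(self):
        ok100 = pair_filter(self._aln(1000, "+"), self._aln(1050, "-"))
        assert isinstance(ok100, AcceptedPair) and ok100.fragment_length == 100
        ok500 = pair_filter(self._aln(1000, "+"), self._aln(1450, "-"))
        assert isinstance(ok500, AcceptedPair) and ok500.fragment_length == 500

    def test_mate_order_irrelevant(self):
        res = pair_filter(self._aln(1250, "-"), self._aln(1000, "+"))
        assert isinstance(res, AcceptedPair) and res.fragment_length == 300

    def test_non_unique_and_diff_chrom(self):
        multi = Alignment("r", "chr1", -1, ".", 0, "multi", 50)
        assert pair_filter(multi, self._aln(100, "-")) == "non_unique"
        other = Alignment("r", "chr2", 100, "-", 0, "unique", 50)
        assert pair_filter(self._aln(100, "+"), other) == "diff_chrom"


class TestReadSam:
    def _write_sam(self, path, body):
        header = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:chr1\tLN:10000\n"
        path.write_text(header + body)

    def test_coordinate_conversion_and_flags(self, tmp_path):
        sam = tmp_path / "a.sam"
        seq = "ACGTACGTAC"
        self._write_sam(
            sam,
            f"r1\t0\tchr1\t101\t60\t10M\t*\t0\t0\t{seq}\tIIIIIIIIII\tNM:i:1\n"
            f"r2\t256\tchr1\t201\t60\t10M\t*\t0\t0\t{seq}\tIIIIIIIIII\n"
            f"r3\t16\tchr1\t301\t60\t10M\t*\t0\t0\t{seq}\tIIIIIIIIII\n"
            f"r4\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\tIIIIIIIIII\n",
        )
        alns = read_sam(str(sam))
        assert [(a.read_id, a.status) for a in alns] == [
            ("r1", "unique"), ("r2", "multi"), ("r3", "unique"), ("r4", "unmapped")]
        assert alns[0].pos == 100 and alns[0].strand == "+" and alns[0].mismatches == 1
        assert alns[2].strand == "-"

    def test_mapq_zero_is_multi(self, tmp_path):
        sam = tmp_path / "b.sam"
        self._write_sam(sam, "r1\t0\tchr1\t11\t0\t5M\t*\t0\t0\tACGTA\tIIIII\n")
        assert read_sam(str(sam))[0].status == "multi"

    def test_missing_header_raises(self, tmp_path):
        sam = tmp_path / "c.sam"
        sam.write_text("@HD\tVN:1.6\n")
        with pytest.raises(ValueError, match="@SQ"):
            read_sam(str(sam))

    def test_empty_body(self, tmp_path):
        sam = tmp_path / "d.sam"
        self._write_sam(sam, "")
        assert read_sam(str(sam)) == []


class TestPipelineInvariants:
    def test_filter_then_map_equals_map_then_filter(self):
        """QC and mapping commute on the accepted-pair level."""
        rng = np.random.default_rng(12)
        ref = _random_seq(rng, 5000)
        index = ReferenceIndex(ref)
        pairs = []
        for i in range(60):
            start = int(rng.integers(0, 4400))
            insert = int(rng.integers(100, 501))
            frag = ref[start:start + insert]
            r1, r2 = frag[:50], revcomp(frag[-50:])
            if i % 4 == 0:
                r1 = "NNN" + r1[3:]
            pairs.append(ReadPair(str(i), r1, r2))

        def run(filter_first):
            use = filter_ambiguous(pairs)[0] if filter_first else pairs
            a1 = map_reads([p.seq1 for p in use], index, [p.id for p in use])
            a2 = map_reads([p.seq2 for p in use], index, [p.id for p in use])
            accepted, _ = accept_pairs(a1, a2)
            if not filter_first:
                ok = {p.id for p in filter_ambiguous(pairs)[0]}
                accepted = [a for a in accepted if a.alignment1.read_id in ok]
            return {(a.alignment1.read_id, a.alignment1.pos, a.fragment_length)
                    for a in accepted}

        assert run(True) == run(False)

    def test_accepted_pairs_recover_true_origin(self, clean_experiment):
        """error_rate=0, no decoys: every accepted pair maps to its origin."""
        cfg, ref, truth, reads = clean_experiment
        index = ReferenceIndex(ref.sequence, ref.chrom)
        subset = reads[:2000]
        a1 = map_reads([r[1] for r in subset], index, [r[0] for r in subset])
        a2 = map_reads([r[2] for r in subset], index, [r[0] for r in subset])
        accepted, reasons = accept_pairs(a1, a2)
        assert len(accepted) > 1900  # near-total acceptance for clean data
        for pair in accepted:
            start, _ = truth.read_origin[pair.alignment1.read_id]
            assert pair.alignment1.pos == start
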