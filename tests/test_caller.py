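"""Seed index, split-read mapping, junction clustering, pairing, export."""

import pytest

from treccap.caller import (
    SeedIndex,
    calls_to_vcf,
    detect_junctions,
    index_reference,
    map_pairs,
    map_read,
    pair_junctions,
)
from treccap.rss import revcomp
from treccap.simulate import (
    NO_TRIM,
    ReadPair,
    insert_trec,
    recombine_dj,
    reference_allele,
    simulate_reads,
)


@pytest.fixture(scope="module")
def trec_allele(ref):
    _, circle = recombine_dj(
        ref, ref.segment("TRD", "Dd2"), ref.segment("TRD", "Dd3"), NO_TRIM, seed=1
    )
    return insert_trec(ref, circle, ("ZFP36L2_region", 8000), NO_TRIM, 0)


def junction_reads(allele, jpos, n, read_len=150, prefix="jr"):
    """n error-free reads, each placed to span allele position jpos."""
    reads = []
    for i in range(n):
        off = 20 + (i * 7) % (read_len - 40)  # junction sits 20..read_len-20 in
        start = jpos - off
        reads.append(
            ReadPair(f"{prefix}{i}", allele.sequence[start : start + read_len], "")
        )
    return reads


class TestIndex:
    def test_k_validation(self, ref):
        with pytest.raises(ValueError, match="odd"):
            SeedIndex(ref, 16)
        with pytest.raises(ValueError):
            SeedIndex(ref, 9)

    def test_unique_kmer_lookup(self, ref, index):
        kmer = ref.contigs["TRD"][1000:1017]
        hits = index.query(kmer)
        assert ("TRD", 1000, "+") in hits
        rc_hits = index.query(revcomp(kmer))
        assert ("TRD", 1000, "-") in rc_hits

    def test_absent_kmer(self, index):
        # a 17-mer over a 2-letter alphabet with long homopolymer runs is
        # effectively absent from uniform random background
        assert index.query("A" * 17) == []


class TestMapRead:
    def test_full_read_single_segment(self, ref, index):
        read = ref.contigs["TRB"][5000:5150]
        aln = map_read(index, read, "r1")
        assert len(aln.segments) == 1
        seg = aln.segments[0]
        assert (seg.contig, seg.ref_start, seg.ref_end) == ("TRB", 5000, 5150)
        assert seg.mismatches == 0
        assert aln.junction is None

    def test_reverse_strand_read(self, ref, index):
        read = revcomp(ref.contigs["TRB"][5000:5150])
        aln = map_read(index, read, "r1")
        assert len(aln.segments) == 1
        assert aln.strand == "-"
        assert aln.segments[0].ref_start == 5000

    def test_junction_read_splits_at_truth(self, ref, index, trec_allele):
        # left pseudo-hybrid junction: partner ends at 8000, insert starts
        # at TRD:4009
        read = trec_allele.sequence[8000 - 70 : 8000 + 80]
        aln = map_read(index, read, "r1")
        assert len(aln.segments) == 2
        j = aln.junction
        t = trec_allele.truth[0]
        assert (j.contig_e, j.pos_e, j.contig_s, j.pos_s) == (
            t.contig_a, t.pos_a, t.contig_b, t.pos_b,
        )

    def test_untemplated_gap_recovered(self, ref, index):
        a = ref.contigs["TRD"]
        b = ref.contigs["ZFP36L2_region"]
        # choose each gap base so it can be absorbed into neither flank's
        # reference continuation (mapping is parsimonious about gap length)
        gap = "".join(
            next(c for c in "ACGT" if c != a[1070 + i] and c != b[4990 + i])
            for i in range(10)
        )
        read = a[1000:1070] + gap + b[5000:5070]
        aln = map_read(index, read, "r1")
        j = aln.junction
        assert j is not None
        assert j.untemplated == gap
        assert (j.pos_e, j.pos_s) == (1070, 5000)
        assert j.mh_len == 0

    def test_unmapped_read(self, index):
        assert map_read(index, "ACGT" * 40, "r1").segments == []


class TestDetect:
    def test_thirty_reads_one_call(self, ref, index, trec_allele):
        reads = junction_reads(trec_allele, 8000, 30)
        alns = [map_read(index, r.seq1, r.name) for r in reads]
        calls = detect_junctions(alns, ref, min_support=3)
        assert len(calls) == 1
        c = calls[0]
        t = trec_allele.truth[0]
        assert c.side_a == (t.contig_a, t.pos_a, "ends_at")
        assert c.side_b == (t.contig_b, t.pos_b, "starts_at")
        assert c.support == 30
        # mutual exclusivity of microhomology and untemplated sequence
        assert not (c.microhomology_len > 0 and c.untemplated_seq)

    def test_min_support_threshold(self, ref, index, trec_allele):
        reads = junction_reads(trec_allele, 8000, 30)
        alns = [map_read(index, r.seq1, r.name) for r in reads]
        assert detect_junctions(alns, ref, min_support=31) == []

    def test_distinct_junctions_not_merged(self, ref, index, trec_allele):
        reads = junction_reads(trec_allele, 8000, 10, prefix="L") + junction_reads(
            trec_allele, 18000, 10, prefix="R"
        )
        alns = [map_read(index, r.seq1, r.name) for r in reads]
        calls = detect_junctions(alns, ref, min_support=3)
        assert len(calls) == 2

    def test_empty_input(self, ref):
        assert detect_junctions([], ref) == []

    def test_no_calls_on_reference_only_reads(self, ref, index):
        # specificity: reads from the unmodified reference yield nothing
        alleles = [reference_allele(ref, c) for c in sorted(ref.contigs)]
        pairs = simulate_reads(alleles, ref.panel, 100, 150, err_rate=0.002, seed=2)
        assert len(pairs) > 500
        calls = detect_junctions(map_pairs(index, pairs), ref, min_support=3)
        assert calls == []


class TestPairing:
    def test_insertion_junctions_pair(self, ref, index, trec_allele):
        pairs = simulate_reads([trec_allele], ref.panel, 60, 150, err_rate=0.0, seed=7)
        calls = detect_junctions(map_pairs(index, pairs), ref)
        cands = pair_junctions(calls, ref)
        assert [len(c.junctions) for c in cands] == [2]

    def test_two_insertions_no_cross_pairing(self, ref, index):
        _, circle = recombine_dj(
            ref, ref.segment("TRB", "Db2"), ref.segment("TRB", "Jb2-3"), NO_TRIM, 1
        )
        a1 = insert_trec(ref, circle, ("ZFP36L2_region", 6000), NO_TRIM, 0)
        a2 = insert_trec(ref, circle, ("MORN3_region", 5000), NO_TRIM, 0)
        pairs = simulate_reads([a1, a2], ref.panel, 60, 150, err_rate=0.0, seed=8)
        calls = detect_junctions(map_pairs(index, pairs), ref)
        cands = pair_junctions(calls, ref)
        paired = [c for c in cands if c.paired]
        assert len(paired) == 2
        for c in paired:
            partner_contigs = {
                s[0] for j in c.junctions for s in (j.side_a, j.side_b)
                if s[0] not in ref.tr_contigs()
            }
            assert len(partner_contigs) == 1

    def test_lone_junction_stays_single(self, ref, index):
        from treccap.simulate import make_translocation

        dd2 = ref.segment("TRD", "Dd2")
        der1, _ = make_translocation(
            ref, (dd2, "3p"), ("ZFP36L2_region", 7000), "type2", NO_TRIM, 0
        )
        pairs = simulate_reads([der1], ref.panel, 60, 150, err_rate=0.0, seed=9)
        calls = detect_junctions(map_pairs(index, pairs), ref)
        cands = pair_junctions(calls, ref)
        assert len(cands) == 1 and not cands[0].paired


class TestExport:
    def test_vcf_bnd_records(self, ref, index, trec_allele):
        pairs = simulate_reads([trec_allele], ref.panel, 60, 150, err_rate=0.0, seed=7)
        calls = detect_junctions(map_pairs(index, pairs), ref)
        vcf = calls_to_vcf(calls, ref)
        body = [l for l in vcf.splitlines() if l and not l.startswith("#")]
        assert len(body) == 2 * len(calls)
        for line in body:
            chrom, pos, vid, ref_base, alt, _, _, info = line.split("\t")
            assert chrom in ref.contigs
            assert ("[" in alt) or ("]" in alt)
            assert "SVTYPE=BND" in info and "MATEID=" in info
        # mate ids are reciprocal
        ids = [l.split("\t")[2] for l in body]
        mates = [l.split("\t")[7].split("MATEID=")[1] for l in body]
        assert sorted(ids) == sorted(mates)
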