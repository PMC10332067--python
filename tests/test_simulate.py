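"""Recombination mechanics: conservation, signal joints, noise, reads."""

import dataclasses

import numpy as np
import pytest

from treccap.rss import revcomp
from treccap.simulate import (
    NO_TRIM,
    SimulationError,
    TrimParams,
    insert_trec,
    make_translocation,
    plant_cryptic_rss,
    recombine_dj,
    reference_allele,
    simulate_reads,
    left_shift,
)


@pytest.fixture(scope="module")
def trd_circle(ref):
    _, circle = recombine_dj(
        ref, ref.segment("TRD", "Dd2"), ref.segment("TRD", "Dd3"), NO_TRIM, seed=1
    )
    return circle


class TestRecombine:
    @pytest.mark.parametrize(
        "locus,up,down,expected_len",
        [("TRD", "Dd2", "Dd3", 10_000), ("TRB", "Db2", "Jb2-3", 1_200)],
    )
    def test_circle_length_equals_excision_distance(
        self, ref, locus, up, down, expected_len
    ):
        _, circle = recombine_dj(
            ref, ref.segment(locus, up), ref.segment(locus, down), NO_TRIM, seed=0
        )
        assert circle.length == expected_len

    def test_conservation_with_no_trimming(self, ref):
        d, j = ref.segment("TRD", "Dd2"), ref.segment("TRD", "Dd3")
        allele, circle = recombine_dj(ref, d, j, NO_TRIM, seed=0)
        cut_a, cut_b = ref.excision_boundaries("TRD", "Dd2", "Dd3")
        rebuilt = allele.sequence[:cut_a] + circle.sequence + allele.sequence[cut_a:]
        assert rebuilt == ref.contigs["TRD"]

    def test_signal_joint_is_blunt_heptamer_fusion(self, ref, trd_circle):
        d, j = ref.segment("TRD", "Dd2"), ref.segment("TRD", "Dd3")
        hept_d = d.rss_3prime.motif.heptamer
        hept_j = j.rss_5prime.motif.heptamer
        # head-to-head fusion with zero untemplated bases: the 14-mer at the
        # circle closure is the J-side heptamer (reverse-complemented on this
        # strand) followed by the D-side heptamer
        assert trd_circle.signal_joint_14mer() == revcomp(hept_j) + hept_d

    def test_12_23_rule_enforced(self, ref):
        d = ref.segment("TRD", "Dd2")
        j = ref.segment("TRD", "Dd3")
        # rebuild the downstream segment with a 23-spacer 5' RSS: 23/23 pairing
        bad_motif = dataclasses.replace(j.rss_5prime.motif, spacer_len=23)
        bad_rss = dataclasses.replace(j.rss_5prime, motif=bad_motif)
        bad_j = dataclasses.replace(j, rss_5prime=bad_rss)
        with pytest.raises(SimulationError, match="12/23"):
            recombine_dj(ref, d, bad_j, NO_TRIM, seed=0)

    def test_seeded_determinism(self, ref):
        d, j = ref.segment("TRD", "Dd2"), ref.segment("TRD", "Dd3")
        trim = TrimParams(8, 10, 1.0, 1.0)
        a1, _ = recombine_dj(ref, d, j, trim, seed=42)
        a2, _ = recombine_dj(ref, d, j, trim, seed=42)
        assert a1.sequence == a2.sequence
        assert a1.truth == a2.truth


class TestInsertTrec:
    def test_full_circle_insertion_geometry(self, ref, trd_circle):
        allele = insert_trec(ref, trd_circle, ("ZFP36L2_region", 8000), NO_TRIM, 0)
        assert len(allele.sequence) == len(ref.contigs["ZFP36L2_region"]) + 10_000
        assert allele.insert_span == ("TRD", 4009, 14009)
        # both junctions flanked by intact heptamers on the insert side
        hept = ref.segment("TRD", "Dd2").rss_3prime.motif.heptamer
        assert allele.sequence[8000 : 8000 + 7] == hept
        assert allele.sequence[18000 - 7 : 18000] == revcomp(hept)

    def test_trb_circle_span(self, ref):
        _, circle = recombine_dj(
            ref, ref.segment("TRB", "Db2"), ref.segment("TRB", "Jb2-3"), NO_TRIM, 0
        )
        allele = insert_trec(ref, circle, ("ZFP36L2_region", 9000), NO_TRIM, 0)
        c, s, e = allele.insert_span
        assert (c, e - s) == ("TRB", 1_200)

    def test_forced_deletion_marks_rss_lost(self, ref, trd_circle):
        heavy = TrimParams(max_del_per_end=8, max_n_insert=0, p_del=1.0, p_ins=0.0)
        seen_lost = False
        for seed in range(30):
            allele = insert_trec(
                ref, trd_circle, ("ZFP36L2_region", 8000), heavy, seed
            )
            _, s, e = allele.insert_span
            left, right = allele.truth
            assert (left.note == "RSS not identifiable") == (s - 4009 >= 8)
            assert (right.note == "RSS not identifiable") == (14009 - e >= 8)
            seen_lost |= bool(left.note or right.note)
        assert seen_lost

    def test_position_outside_contig_rejected(self, ref, trd_circle):
        with pytest.raises(SimulationError, match="outside contig"):
            insert_trec(ref, trd_circle, ("ZFP36L2_region", 10**6), NO_TRIM, 0)


class TestTranslocation:
    def test_reciprocal_conservation(self, ref):
        dd2 = ref.segment("TRD", "Dd2")
        der1, der2 = make_translocation(
            ref, (dd2, "3p"), ("ZFP36L2_region", 7000), "type2", NO_TRIM, 0
        )
        cut = dd2.rss_3prime.cleavage_edge
        trd, z = ref.contigs["TRD"], ref.contigs["ZFP36L2_region"]
        assert der1.sequence == trd[:cut] + z[7000:]
        assert der2.sequence == z[:7000] + trd[cut:]
        assert len(der1.sequence) + len(der2.sequence) == len(trd) + len(z)

    def test_type1_requires_cryptic_rss(self, ref):
        dd2 = ref.segment("TRD", "Dd2")
        with pytest.raises(SimulationError, match="cryptic RSS"):
            make_translocation(
                ref, (dd2, "3p"), ("ZFP36L2_region", 7000), "type1", NO_TRIM, 0
            )
        planted = plant_cryptic_rss(ref, "ZFP36L2_region", 7000)
        der1, _ = make_translocation(
            planted, (dd2, "3p"), ("ZFP36L2_region", 7000), "type1", NO_TRIM, 0
        )
        assert der1.truth[0].event_class == "translocation_type1"

    def test_tr_partner_is_trans_rearrangement(self, ref):
        dd2 = ref.segment("TRD", "Dd2")
        jg1 = ref.segment("TRG", "Jg1")
        der1, der2 = make_translocation(
            ref, (dd2, "3p"), ("TRG", jg1.rss_5prime.cleavage_edge),
            "type2", NO_TRIM, 0,
        )
        assert {t.event_class for t in der1.truth + der2.truth} == {
            "trans_rearrangement"
        }


class TestReads:
    def test_error_free_reads_are_allele_substrings(self, ref, trd_circle):
        allele = insert_trec(ref, trd_circle, ("ZFP36L2_region", 8000), NO_TRIM, 0)
        pairs = simulate_reads([allele], ref.panel, 30, 150, err_rate=0.0, seed=3)
        assert pairs
        for p in pairs[:50]:
            name, fs, fe, _ = p.name.rsplit("|", 3)
            fs, fe = int(fs), int(fe)
            frag = allele.sequence[fs:fe]
            assert p.seq1 == frag[:150]
            assert p.seq2 == revcomp(frag)[:150]

    def test_each_junction_spanned_despite_unbaited_partner(self, ref, trd_circle):
        # panel has no partner-gene baits; TR-side anchoring must suffice
        allele = insert_trec(ref, trd_circle, ("ZFP36L2_region", 8000), NO_TRIM, 0)
        pairs = simulate_reads([allele], ref.panel, 100, 150, err_rate=0.0, seed=4)
        junction_allele_pos = [8000, 18000]
        for jpos in junction_allele_pos:
            spanning = [
                p for p in pairs
                if int(p.name.rsplit("|", 3)[1]) < jpos - 20
                and int(p.name.rsplit("|", 3)[2]) > jpos + 20
            ]
            assert len(spanning) >= 1

    def test_captured_fragments_project_onto_panel(self, ref):
        bg = reference_allele(ref, "ZFP36L2_region")  # no baits on this contig
        assert simulate_reads([bg], ref.panel, 50, 150, err_rate=0.0, seed=5) == []

    def test_determinism_and_error_rate(self, ref, trd_circle):
        allele = insert_trec(ref, trd_circle, ("ZFP36L2_region", 8000), NO_TRIM, 0)
        a = simulate_reads([allele], ref.panel, 50, 150, err_rate=0.01, seed=6)
        b = simulate_reads([allele], ref.panel, 50, 150, err_rate=0.01, seed=6)
        assert a == b
        # measured substitution rate near the nominal 1%
        clean = simulate_reads([allele], ref.panel, 50, 150, err_rate=0.0, seed=6)
        diffs = sum(
            x != y for pa, pc in zip(a, clean) for x, y in zip(pa.seq1, pc.seq1)
        )
        total = sum(len(p.seq1) for p in a)
        assert 0.005 < diffs / total < 0.02

    def test_parameter_validation(self, ref, trd_circle):
        allele = insert_trec(ref, trd_circle, ("ZFP36L2_region", 8000), NO_TRIM, 0)
        with pytest.raises(SimulationError):
            simulate_reads([allele], ref.panel, 0, 150)
        with pytest.raises(SimulationError):
            simulate_reads([allele], ref.panel, 10, 30)


class TestLeftShift:
    def test_idempotent(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
            pa, pb = left_shift(a, 30, b, 25)
            assert left_shift(a, pa, b, pb) == (pa, pb)

    def test_shifts_through_shared_suffix(self):
        #      a: ...GATT|  b: ...GATT|...  -> slides left past the repeat
        a = "CCCCGATT"
        b = "AAAAGATTTTTT"
        pa, pb = left_shift(a, 8, b, 8)
        assert (pa, pb) == (4, 4)
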