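"""Event classification: TREC insertion, type 1/2 translocation, trans-rearrangement.

Decision rules, applied in order to each junction candidate:

1. a paired candidate whose TR-side breakpoints bound a D-J excised
   interval (matching the RSS cleavage edges of an annotated upstream /
   downstream segment pair, allowing junctional trimming) with the
   regenerated signal ends facing the insert -> TREC insertion, with an
   insertion size (the excised span) and a completeness flag;
2. both sides in TR/IG loci: different loci -> trans-rearrangement
   (same-locus junctions are ordinary rearrangements, not events);
3. a single TR <-> non-TR junction whose partner end carries a cryptic
   RSS -> type 1 translocation;
4. the same without any RSS at the partner end -> type 2 translocation;
5. anything else -> unresolved, with the conflicting evidence recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import rss as rss_mod
from .caller import EventCandidate, JunctionCall, SeedIndex
from .reference import MiniReference

#: tolerance (bp) for matching trimmed breakpoints to RSS cleavage edges;
#: covers the simulator's bounded per-end deletions with margin
DJ_MATCH_SLACK = 25
#: deletions at/beyond this size remove the heptamer entirely
RSS_LOST_DEL = 8
#: untemplated bases that coincidentally match the reference continuation
#: are absorbed into the aligned segment, dragging the canonical breakpoint
#: outward while vanishing from the reported untemplated sequence; allow a
#: few bases of such drift when matching annotated cleavage edges
N_ABSORPTION_SLACK = 6
#: per-sample cap before a QC warning is attached (observed 1-2 per patient)
MAX_EVENTS_PER_SAMPLE = 2

EVENT_CLASSES = (
    "TREC_insertion",
    "translocation_type1",
    "translocation_type2",
    "trans_rearrangement",
    "unresolved",
)


@dataclass
class EventCall:
    sample_id: str
    event_class: str
    tr_locus: str
    tr_segments: str
    partner_gene: str
    insertion_size: Optional[int]
    rss_evidence: Dict[str, str]
    support: int
    completeness: str = ""  # entire | partial | indeterminate (insertions)
    reasons: List[str] = field(default_factory=list)
    junctions: List[JunctionCall] = field(default_factory=list)


class UndefinedSizeError(ValueError):
    """Insertion size requested for a single-junction event."""


def identify_partner(
    ref: MiniReference,
    side: Optional[Tuple[str, int]] = None,
    clip_seq: Optional[str] = None,
    index: Optional[SeedIndex] = None,
) -> str:
    """Partner-gene lookup by coordinate, or by seed-and-extend of a clip.

    With coordinates: interval overlap against the partner catalog.  With
    only a clip consensus (>= 20 bp), the sequence is placed via the seed
    index and the hit coordinate looked up; ambiguous or absent -> "unknown".
    """
    if side is not None:
        p = ref.partner_at(*side)
        return p.name if p else "unknown"
    if clip_seq is None or len(clip_seq) < 20:
        return "unknown"
    if index is None:
        raise ValueError("clip search requires a seed index")
    k = index.k
    if len(clip_seq) < k:
        return "unknown"
    hits = index.query(clip_seq[:k].upper())
    if len(hits) != 1:
        return "unknown"
    contig, pos, _ = hits[0]
    p = ref.partner_at(contig, pos)
    return p.name if p else "unknown"


def _match_dj_interval(
    ref: MiniReference,
    contig: str,
    tr_start: int,
    tr_end: int,
    mh_left: int = 0,
    mh_right: int = 0,
) -> Optional[Tuple[str, str, str, int, int]]:
    """Find segments whose excision boundaries bracket [tr_start, tr_end).

    Returns (locus, upstream name, downstream name, cut_a, cut_b) where
    cut_a/cut_b are the annotated cleavage edges.  Trimming moves the
    observed interval inward; left-shift canonicalization can move a
    breakpoint outward by at most its microhomology length, hence
    cut_a - mh <= tr_start <= cut_a + slack (mirrored on the right).
    """
    segs = [s for s in ref.segments if s.contig == contig]
    for up in segs:
        if up.rss_3prime is None:
            continue
        ca = up.rss_3prime.cleavage_edge
        if not (ca - mh_left <= tr_start <= ca + DJ_MATCH_SLACK):
            continue
        for down in segs:
            if down is up or down.rss_5prime is None:
                continue
            cb = down.rss_5prime.cleavage_edge
            if cb - DJ_MATCH_SLACK <= tr_end <= cb + mh_right and ca < cb:
                return (up.locus, up.name, down.name, ca, cb)
    return None


def infer_insertion_size(event: EventCall) -> int:
    """Excised-span size: distance between the TR-side breakpoints (bp).

    Equals the truth insert length, i.e. the full circle size minus any
    junctional deletions, for simulated insertions.
    """
    if event.insertion_size is None:
        raise UndefinedSizeError(
            f"event {event.sample_id}/{event.event_class} has a single junction; "
            "insertion size is undefined"
        )
    return event.insertion_size


def _snap_to_signal_end(call: JunctionCall, ref: MiniReference) -> JunctionCall:
    """Slide a junction right through its microhomology span so a TR-side
    breakpoint lands on an annotated RSS cleavage edge, when reachable.

    Breakpoints are canonicalized by left-shifting, so a signal-end break
    is ambiguous within ``microhomology_len`` bases and the annotated edge
    (the biological cut site) lies at or right of the canonical position.
    Both sides shift together; the joined sequence is unchanged.
    """
    tr = ref.tr_contigs()
    edges = []
    for s in ref.segments:
        for r in (s.rss_5prime, s.rss_3prime):
            if r is not None:
                edges.append((r.contig, r.cleavage_edge))
    best_d = None
    for contig, pos, _ in (call.side_a, call.side_b):
        if contig not in tr:
            continue
        for ec, ee in edges:
            if ec != contig:
                continue
            d = ee - pos
            if 0 <= d <= call.microhomology_len and (best_d is None or d < best_d):
                best_d = d
        break  # snap on the first TR side only; both sides move together
    if not best_d:
        return call
    ca, pa, oa = call.side_a
    cb, pb, ob = call.side_b
    return JunctionCall(
        (ca, pa + best_d, oa),
        (cb, pb + best_d, ob),
        call.support,
        call.microhomology_len,
        call.untemplated_seq,
        call.consensus_junction_seq,
    )


def classify_event(
    candidate: EventCandidate,
    ref: MiniReference,
    sample_id: str = "",
    rss_window: int = rss_mod.DEFAULT_BREAK_WINDOW,
) -> EventCall:
    """Classify one candidate; annotation of each junction end is computed
    here via the RSS annotator."""
    candidate = EventCandidate(
        [_snap_to_signal_end(j, ref) for j in candidate.junctions]
    )
    tr = ref.tr_contigs()
    anns: Dict[str, str] = {}
    reasons: List[str] = []

    def annotate(contig, pos, label):
        a = rss_mod.annotate_breakpoint_end(contig, pos, ref, rss_window)
        anns[label] = f"{contig}:{pos}={a.category}"
        return a

    support = min(j.support for j in candidate.junctions)

    if candidate.paired:
        j1, j2 = candidate.junctions
        # pair_junctions guarantees: j1 = partner ends_at / TR starts_at,
        # j2 = TR ends_at / partner starts_at
        (pc1, pp1, _), (tc1, tp1, _) = j1.side_a, j1.side_b
        (tc2, tp2, _), (pc2, pp2, _) = j2.side_a, j2.side_b
        ann_tr1 = annotate(tc1, tp1, "tr_left")
        ann_tr2 = annotate(tc2, tp2, "tr_right")
        annotate(pc1, pp1, "partner_left")
        annotate(pc2, pp2, "partner_right")
        # a breakpoint can sit outward of the annotated edge by its
        # microhomology span, or by untemplated bases that happen to match
        # the reference continuation
        tol1 = j1.microhomology_len + len(j1.untemplated_seq) + N_ABSORPTION_SLACK
        tol2 = j2.microhomology_len + len(j2.untemplated_seq) + N_ABSORPTION_SLACK
        match = _match_dj_interval(ref, tc1, tp1, tp2, tol1, tol2)
        if match is not None:
            locus, up, down, ca, cb = match
            size = tp2 - tp1
            if tp1 == ca and tp2 == cb:
                completeness = "entire"
            elif tp1 - ca >= RSS_LOST_DEL or cb - tp2 >= RSS_LOST_DEL:
                completeness = "partial"
                reasons.append("RSS not identifiable on a trimmed insert end")
            else:
                completeness = "indeterminate"
            if ann_tr1.category != "authentic_signal_end" and tp1 != ca:
                reasons.append("left signal end trimmed")
            if ann_tr2.category != "authentic_signal_end" and tp2 != cb:
                reasons.append("right signal end trimmed")
            partner = identify_partner(ref, (pc1, min(pp1, pp2)))
            return EventCall(
                sample_id, "TREC_insertion", locus, f"{up}-{down}", partner,
                size, anns, support, completeness, reasons, list(candidate.junctions),
            )
        reasons.append("paired junctions do not bound an annotated D-J interval")
        return EventCall(
            sample_id, "unresolved", tr.get(tc1, ""), "", "unknown",
            tp2 - tp1 if tp2 > tp1 else None, anns, support, "", reasons,
            list(candidate.junctions),
        )

    (call,) = candidate.junctions
    (ca_, pa, _), (cb_, pb, _) = call.side_a, call.side_b
    a_tr, b_tr = ca_ in tr, cb_ in tr
    if a_tr and b_tr:
        annotate(ca_, pa, "end_a")
        annotate(cb_, pb, "end_b")
        if tr[ca_] != tr[cb_]:
            return EventCall(
                sample_id, "trans_rearrangement", tr[ca_],
                _nearest_segment(ref, ca_, pa), tr[cb_], None, anns, support,
                "", reasons, [call],
            )
        reasons.append("intra-locus rearrangement (ordinary V(D)J joint)")
        return EventCall(
            sample_id, "unresolved", tr[ca_], _nearest_segment(ref, ca_, pa),
            "", None, anns, support, "", reasons, [call],
        )
    if a_tr != b_tr:
        (tcontig, tpos) = (ca_, pa) if a_tr else (cb_, pb)
        (pcontig, ppos) = (cb_, pb) if a_tr else (ca_, pa)
        annotate(tcontig, tpos, "tr_end")
        ann_p = annotate(pcontig, ppos, "partner_end")
        partner = identify_partner(ref, (pcontig, ppos))
        cls = (
            "translocation_type1"
            if ann_p.category == "cryptic_rss"
            else "translocation_type2"
        )
        return EventCall(
            sample_id, cls, tr[tcontig], _nearest_segment(ref, tcontig, tpos),
            partner, None, anns, support, "", reasons, [call],
        )
    annotate(ca_, pa, "end_a")
    annotate(cb_, pb, "end_b")
    reasons.append("no junction side lies in a TR/IG locus")
    return EventCall(
        sample_id, "unresolved", "", "", identify_partner(ref, (ca_, pa)),
        None, anns, support, "", reasons, [call],
    )


def _nearest_segment(ref: MiniReference, contig: str, pos: int) -> str:
    best, dist = "", None
    for s in ref.segments:
        if s.contig != contig:
            continue
        d = min(abs(pos - s.start), abs(pos - s.end))
        if dist is None or d < dist:
            best, dist = s.name, d
    return best


def classify_sample(
    candidates: Sequence[EventCandidate],
    ref: MiniReference,
    sample_id: str = "",
    rss_window: int = rss_mod.DEFAULT_BREAK_WINDOW,
) -> List[EventCall]:
    """Classify all candidates of one sample, dropping ordinary intra-locus
    joints and attaching a QC warning beyond the per-sample event cap."""
    events = []
    for c in candidates:
        e = classify_event(c, ref, sample_id, rss_window)
        if (
            e.event_class == "unresolved"
            and c.paired
            and any("do not bound" in r for r in e.reasons)
        ):
            # a spuriously paired candidate: judge each junction on its own
            events.extend(
                classify_event(EventCandidate([j]), ref, sample_id, rss_window)
                for j in c.junctions
            )
        else:
            events.append(e)
    events = [
        e for e in events
        if not (e.event_class == "unresolved" and
                any("intra-locus" in r for r in e.reasons))
    ]
    informative = [e for e in events if e.event_class != "unresolved"]
    if len(informative) > MAX_EVENTS_PER_SAMPLE:
        for e in informative:
            e.reasons.append(
                f"QC: {len(informative)} independent events in one sample"
            )
    return events


def events_to_table(events: Sequence[EventCall]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "event_class": e.event_class,
                "tr_locus": e.tr_locus,
                "tr_segments": e.tr_segments,
                "partner_gene": e.partner_gene,
                "insertion_size": e.insertion_size,
                "support": e.support,
                "completeness": e.completeness,
                "rss_evidence": ";".join(f"{k}:{v}" for k, v in e.rss_evidence.items()),
                "reasons": ";".join(e.reasons),
            }
            for e in events
        ],
        columns=[
            "sample_id", "event_class", "tr_locus", "tr_segments",
            "partner_gene", "insertion_size", "support", "completeness",
            "rss_evidence", "reasons",
        ],
    )
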