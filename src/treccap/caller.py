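"""Split-read junction detection against the mini-reference.

Mapping is k-mer seeded, ungapped extension: each read is anchored by its
leftmost and rightmost uniquely-placed seeds; if the two anchors disagree
in diagonal or contig, the read is split at the mismatch-optimal point,
allowing a short untemplated gap.  Breakpoints are canonicalized by
left-shifting through microhomology to the lowest reference coordinates,
the same rule the simulator applies to truth coordinates.

Junction-supporting reads are clustered within a window; each cluster
becomes a :class:`JunctionCall` with modal breakpoints, distinct read-pair
support, microhomology/untemplated accounting, and a consensus junction
sequence.  Calls can be exported as TSV or VCF 4.2 breakend (BND) records.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .reference import MiniReference
from .rss import revcomp
from .simulate import ReadPair

#: defaults chosen for a desk-scale reference with unique 17-mers
DEFAULT_K = 17
DEFAULT_MAX_MISMATCH_RATE = 0.05
DEFAULT_MIN_SUPPORT = 3
DEFAULT_CLUSTER_WINDOW = 10
DEFAULT_PAIRING_WINDOW = 100
# Per untemplated base, traded against mismatches: a random untemplated
# base mismatches the reference continuation with probability 3/4, so the
# penalty must be < 0.75 to open true gaps; keeping it below ~0.4 also wins
# when a minority of gap bases happen to match the far side (frequent at
# heptamer-flanked signal-end junctions, where both continuations are
# near-identical RSS sequence).
_GAP_PENALTY = 0.35
_MAX_GAP = 15
_MIN_SEGMENT = 15


class SeedIndex:
    """Exact-match k-mer index over the plus strand of every contig.

    Queries check both the k-mer and its reverse complement, so both
    strands are represented canonically.
    """

    def __init__(self, ref: MiniReference, k: int = DEFAULT_K):
        if not (11 <= k <= 31):
            raise ValueError("k must be in [11, 31]")
        if k % 2 == 0:
            raise ValueError("k must be odd (even k admits palindromic seeds)")
        self.k = k
        self.ref = ref
        self._table: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
        for contig, seq in ref.contigs.items():
            for i in range(len(seq) - k + 1):
                self._table[seq[i : i + k]].append((contig, i))
        self._table = dict(self._table)

    def query(self, kmer: str) -> List[Tuple[str, int, str]]:
        """All placements of ``kmer``: (contig, plus-strand pos, strand)."""
        out = [(c, p, "+") for c, p in self._table.get(kmer, ())]
        out += [(c, p, "-") for c, p in self._table.get(revcomp(kmer), ())]
        return out


def index_reference(ref: MiniReference, k: int = DEFAULT_K) -> SeedIndex:
    return SeedIndex(ref, k)


@dataclass(frozen=True)
class AlignmentSegment:
    read_id: str
    read_start: int
    read_end: int
    contig: str
    ref_start: int
    ref_end: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class JunctionObs:
    """One read's evidence for a junction: side E ends at pos_e, side S
    starts at pos_s (allele orientation, canonicalized)."""

    contig_e: str
    pos_e: int
    contig_s: str
    pos_s: int
    mh_len: int
    untemplated: str
    read_id: str


@dataclass
class ReadAlignment:
    read_id: str
    strand: str
    segments: List[AlignmentSegment]
    junction: Optional[JunctionObs] = None
    ambiguous: bool = False


def _unique_anchor(index: SeedIndex, read: str, offsets) -> Optional[Tuple[int, str, int, str]]:
    """First offset whose seed places uniquely: (offset, contig, pos, strand)."""
    for off in offsets:
        hits = index.query(read[off : off + index.k])
        if len(hits) == 1:
            c, p, s = hits[0]
            return off, c, p, s
        # multi-hit or absent: keep scanning
    return None


def map_read(
    index: SeedIndex,
    read: str,
    read_id: str = "",
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> ReadAlignment:
    """Greedy seeded, ungapped mapping of one read.

    A read crossing one junction yields two segments partitioning it up
    to the microhomology / untemplated gap; an unmappable remainder is
    left soft-clipped (absent from segments).  Reads whose every seed is
    multi-mapping are flagged ambiguous and contribute no evidence.
    """
    read = read.upper()
    n = len(read)
    k = index.k
    if n < k:
        return ReadAlignment(read_id, "+", [])
    step = max(1, k // 2)
    fwd_offsets = list(range(0, n - k + 1, step))
    if fwd_offsets[-1] != n - k:
        fwd_offsets.append(n - k)
    left = _unique_anchor(index, read, fwd_offsets)
    if left is None:
        any_hit = any(index.query(read[o : o + k]) for o in fwd_offsets)
        return ReadAlignment(read_id, "+", [], ambiguous=any_hit)
    if left[3] == "-":
        aln = map_read(index, revcomp(read), read_id, max_mismatch_rate)
        # junction geometry is strand-invariant after normalization
        aln.strand = "-"
        return aln

    right = _unique_anchor(index, read, reversed(fwd_offsets))
    assert right is not None  # left anchor exists
    off_l, contig_a, pos_a, _ = left
    off_r, contig_b, pos_b, strand_r = right
    ref = index.ref
    diag_a = pos_a - off_l
    if strand_r == "-":
        # discordant strands within one read: treat right side as unmapped
        contig_b, diag_b = contig_a, diag_a
    else:
        diag_b = pos_b - off_r

    seq_a = ref.contigs[contig_a]
    seq_b = ref.contigs[contig_b]

    def mism_profile(seq: str, diag: int) -> np.ndarray:
        out = np.ones(n, dtype=np.int32)
        lo = max(0, -diag)
        hi = min(n, len(seq) - diag)
        for i in range(lo, hi):
            if read[i] == seq[diag + i]:
                out[i] = 0
        return out

    if contig_a == contig_b and diag_a == diag_b:
        m = mism_profile(seq_a, diag_a)
        total = int(m.sum())
        seg = AlignmentSegment(
            read_id, 0, n, contig_a, diag_a, diag_a + n, "+", total
        )
        return ReadAlignment(read_id, "+", [seg])

    cum_a = np.concatenate([[0], np.cumsum(mism_profile(seq_a, diag_a))])
    cum_b = np.concatenate([[0], np.cumsum(mism_profile(seq_b, diag_b))])
    best = None  # (score, g, s)
    for g in range(0, _MAX_GAP + 1):
        if g > n:
            break
        totals = cum_a[: n - g + 1] + (cum_b[n] - cum_b[g : n + 1]) + _GAP_PENALTY * g
        s = int(np.argmin(totals))
        score = float(totals[s])
        if best is None or score < best[0] - 1e-9:
            best = (score, g, s)
    _, g, s = best

    segments = []
    junction = None
    mism_a = int(cum_a[s])
    mism_b = int(cum_b[n] - cum_b[s + g])
    len_a, len_b = s, n - s - g
    ok_a = len_a >= _MIN_SEGMENT and mism_a <= max(1, max_mismatch_rate * len_a)
    ok_b = len_b >= _MIN_SEGMENT and mism_b <= max(1, max_mismatch_rate * len_b)
    if ok_a:
        segments.append(
            AlignmentSegment(read_id, 0, s, contig_a, diag_a, diag_a + s, "+", mism_a)
        )
    if ok_b:
        segments.append(
            AlignmentSegment(
                read_id, s + g, n, contig_b, diag_b + s + g, diag_b + n, "+", mism_b
            )
        )
    if ok_a and ok_b:
        end_a = diag_a + s
        start_b = diag_b + s + g
        untemplated = read[s : s + g]
        mh = 0
        if g == 0:
            while (
                end_a > 0
                and start_b > 0
                and seq_a[end_a - 1] == seq_b[start_b - 1]
            ):
                end_a -= 1
                start_b -= 1
            while (
                mh < 20
                and end_a + mh < len(seq_a)
                and start_b + mh < len(seq_b)
                and seq_a[end_a + mh] == seq_b[start_b + mh]
            ):
                mh += 1
        junction = JunctionObs(
            contig_a, end_a, contig_b, start_b, mh, untemplated, read_id
        )
    return ReadAlignment(read_id, "+", segments, junction)


def map_pairs(
    index: SeedIndex,
    pairs: Iterable[ReadPair],
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> List[ReadAlignment]:
    out = []
    for p in pairs:
        out.append(map_read(index, p.seq1, p.name, max_mismatch_rate))
        out.append(map_read(index, p.seq2, p.name, max_mismatch_rate))
    return out


@dataclass(frozen=True)
class JunctionCall:
    """A clustered, base-resolution junction.

    ``side_a`` (ends_at) and ``side_b`` (starts_at) follow the derived
    allele's orientation; microhomology and untemplated sequence are
    mutually exclusive by the left-shift convention.
    """

    side_a: Tuple[str, int, str]  # (contig, pos, "ends_at")
    side_b: Tuple[str, int, str]  # (contig, pos, "starts_at")
    support: int
    microhomology_len: int
    untemplated_seq: str
    consensus_junction_seq: str


def detect_junctions(
    alignments: Sequence[ReadAlignment],
    ref: MiniReference,
    min_support: int = DEFAULT_MIN_SUPPORT,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
) -> List[JunctionCall]:
    """Cluster per-read junction observations into calls.

    Observations agreeing within ``cluster_window`` on both sides are
    merged; the reported breakpoint is the modal position, support counts
    distinct read pairs, and the consensus junction sequence is the modal
    junction context.  Calls are sorted by (contig, pos).
    """
    by_pair: Dict[Tuple[str, str], List[JunctionObs]] = defaultdict(list)
    for aln in alignments:
        if aln.junction is not None:
            j = aln.junction
            by_pair[(j.contig_e, j.contig_s)].append(j)

    calls: List[JunctionCall] = []
    for (ce, cs), obs in by_pair.items():
        obs.sort(key=lambda o: (o.pos_e, o.pos_s))
        clusters: List[List[JunctionObs]] = []
        for o in obs:
            placed = False
            for cl in clusters:
                me = Counter((x.pos_e, x.pos_s) for x in cl).most_common(1)[0][0]
                if abs(o.pos_e - me[0]) <= cluster_window and abs(o.pos_s - me[1]) <= cluster_window:
                    cl.append(o)
                    placed = True
                    break
            if not placed:
                clusters.append([o])
        for cl in clusters:
            support = len({o.read_id for o in cl})
            if support < min_support:
                continue
            (pos_e, pos_s), _ = Counter((o.pos_e, o.pos_s) for o in cl).most_common(1)[0]
            modal = [o for o in cl if (o.pos_e, o.pos_s) == (pos_e, pos_s)]
            mh, _ = Counter(o.mh_len for o in modal).most_common(1)[0]
            unt, _ = Counter(o.untemplated for o in modal).most_common(1)[0]
            if mh > 0:
                unt = ""
            flank_e = ref.contigs[ce][max(0, pos_e - 20) : pos_e]
            flank_s = ref.contigs[cs][pos_s : pos_s + 20]
            calls.append(
                JunctionCall(
                    (ce, pos_e, "ends_at"),
                    (cs, pos_s, "starts_at"),
                    support,
                    mh,
                    unt,
                    flank_e + unt.lower() + flank_s,
                )
            )
    calls.sort(key=lambda c: (c.side_a[0], c.side_a[1], c.side_b[0], c.side_b[1]))
    return calls


@dataclass
class EventCandidate:
    """One or two junction calls hypothesized to form a single event."""

    junctions: List[JunctionCall]

    @property
    def paired(self) -> bool:
        return len(self.junctions) == 2


#: reciprocal-translocation junction pairs share (almost) one TR position;
#: a genuine excised insert spans at least this many bases
MIN_EXCISED_SPAN = 50


def pair_junctions(
    calls: Sequence[JunctionCall],
    ref: MiniReference,
    pairing_window: int = DEFAULT_PAIRING_WINDOW,
) -> List[EventCandidate]:
    """Pair the two pseudo-hybrid junctions of an insertion event.

    Two calls pair when their non-TR (partner) positions lie within
    ``pairing_window`` on the same contig and their TR-side positions
    bound a plausible excised interval (>= ``MIN_EXCISED_SPAN`` bp) on one
    TR contig.  Unpaired calls become single-junction candidates.
    """
    tr = ref.tr_contigs()

    def split(call: JunctionCall):
        (ca, pa, _), (cb, pb, _) = call.side_a, call.side_b
        a_tr, b_tr = ca in tr, cb in tr
        if a_tr == b_tr:
            return None
        if b_tr:  # partner ends_at, TR starts_at: insert left junction
            return ("left", ca, pa, cb, pb)
        return ("right", cb, pb, ca, pa)  # TR ends_at, partner starts_at

    lefts, rights, used = [], [], set()
    for i, c in enumerate(calls):
        info = split(c)
        if info and info[0] == "left":
            lefts.append((i, info))
        elif info and info[0] == "right":
            rights.append((i, info))

    candidates: List[EventCandidate] = []
    for i, (_, pc_l, pp_l, tc_l, tp_l) in lefts:
        best = None
        for jdx, (j, (_, pc_r, pp_r, tc_r, tp_r)) in enumerate(rights):
            if j in used or pc_l != pc_r or tc_l != tc_r:
                continue
            if abs(pp_l - pp_r) > pairing_window:
                continue
            if tp_r - tp_l < MIN_EXCISED_SPAN:
                continue
            if best is None or abs(pp_l - pp_r) < best[0]:
                best = (abs(pp_l - pp_r), j)
        if best is not None:
            used.add(best[1])
            used.add(i)
            candidates.append(
                EventCandidate([calls[i], calls[best[1]]])
            )
    for i, c in enumerate(calls):
        if i not in used:
            candidates.append(EventCandidate([c]))
    return candidates


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def calls_to_table(calls: Sequence[JunctionCall]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "contig_a": c.side_a[0],
                "pos_a": c.side_a[1],
                "orient_a": c.side_a[2],
                "contig_b": c.side_b[0],
                "pos_b": c.side_b[1],
                "orient_b": c.side_b[2],
                "support": c.support,
                "microhomology_len": c.microhomology_len,
                "untemplated_seq": c.untemplated_seq,
                "consensus_junction_seq": c.consensus_junction_seq,
            }
            for c in calls
        ],
        columns=[
            "contig_a", "pos_a", "orient_a", "contig_b", "pos_b", "orient_b",
            "support", "microhomology_len", "untemplated_seq",
            "consensus_junction_seq",
        ],
    )


def calls_to_vcf(calls: Sequence[JunctionCall], ref: MiniReference) -> str:
    """Render calls as VCF 4.2 symbolic breakend (BND) records."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting read pairs">',
        '##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Microhomology length">',
    ]
    for c in sorted(ref.contigs):
        lines.append(f"##contig=<ID={c},length={len(ref.contigs[c])}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, c in enumerate(calls):
        ca, pa, _ = c.side_a  # last base of side A is 0-based pa-1 -> VCF POS pa
        cb, pb, _ = c.side_b  # first base of side B is 0-based pb -> VCF POS pb+1
        ref_a = ref.contigs[ca][pa - 1] if pa > 0 else "N"
        ref_b = ref.contigs[cb][pb]
        ins = c.untemplated_seq
        ida, idb = f"bnd_{i}a", f"bnd_{i}b"
        info = f"SVTYPE=BND;SUPPORT={c.support};HOMLEN={c.microhomology_len}"
        lines.append(
            f"{ca}\t{pa}\t{ida}\t{ref_a}\t{ref_a}{ins}[{cb}:{pb + 1}[\t.\tPASS\t"
            f"{info};MATEID={idb}"
        )
        lines.append(
            f"{cb}\t{pb + 1}\t{idb}\t{ref_b}\t]{ca}:{pa}]{ins}{ref_b}\t.\tPASS\t"
            f"{info};MATEID={ida}"
        )
    return "\n".join(lines) + "\n"
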