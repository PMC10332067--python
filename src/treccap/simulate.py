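"""V(D)J recombination, TREC formation/reinsertion, translocation and read simulation.

This module is the package's ground-truth generator.  It models:

* D-J rearrangement under the 12/23 rule: RAG cleavage exactly at the
  heptamer/segment boundaries, coding-joint formation with optional
  exonucleolytic deletions and untemplated (N) additions, and excision of
  the intervening DNA as an episomal circle whose blunt signal ends fuse
  head-to-head into a signal joint;
* reinsertion of an excision circle into a partner gene, re-opened at the
  signal joint so the two regenerated blunt RSS ends form two
  pseudo-hybrid junctions;
* reciprocal translocations between a TR segment break and a partner
  break, with (type 1) or without (type 2) a cryptic RSS at the partner
  side, and trans-rearrangements when the partner break is in another
  TR/IG locus;
* paired-end capture sequencing: fragments are retained only if they
  project onto a panel interval, with per-base substitution errors.

Every derived allele carries machine-checkable truth: its block structure
(which reference intervals compose it) and the canonicalized junction
coordinates, so callers can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .reference import MiniReference, ReferenceError, SegmentAnnotation
from .rss import revcomp

BASES = "ACGT"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class TrimParams:
    """Junctional-noise model: per-end deletions and untemplated additions."""

    max_del_per_end: int = 8
    max_n_insert: int = 10
    p_del: float = 0.5
    p_ins: float = 0.5

    def __post_init__(self):
        if not (0 <= self.p_del <= 1 and 0 <= self.p_ins <= 1):
            raise SimulationError("probabilities must lie in [0,1]")
        if self.max_del_per_end < 0 or self.max_n_insert < 0:
            raise SimulationError("maxima must be >= 0")
        if self.max_del_per_end > 15 or self.max_n_insert > 15:
            raise SimulationError("per-end trimming maxima are bounded at 15")


NO_TRIM = TrimParams(0, 0, 0.0, 0.0)
DEFAULT_TRIM = TrimParams()


def _sample_del(trim: TrimParams, rng: np.random.Generator) -> int:
    if trim.max_del_per_end == 0 or rng.random() >= trim.p_del:
        return 0
    return int(rng.integers(1, trim.max_del_per_end + 1))


def _sample_n(trim: TrimParams, rng: np.random.Generator) -> str:
    if trim.max_n_insert == 0 or rng.random() >= trim.p_ins:
        return ""
    n = min(int(rng.geometric(0.4)), trim.max_n_insert)
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@dataclass(frozen=True)
class TrecCircle:
    """An excised episomal circle carrying a blunt signal joint.

    ``sequence`` is the excised fragment stored linearly; the circle is
    closed between its last and first base, which is exactly where the two
    blunt signal ends fuse (``signal_joint_offset`` = 0 in circular
    coordinates).  The first 7 bases are the upstream segment's heptamer
    in consensus orientation; the last 7 are the downstream segment's
    heptamer (reverse-complemented on this strand).
    """

    sequence: str
    source: Tuple[str, str, str]  # (locus, upstream segment, downstream segment)
    ref_contig: str
    ref_start: int  # excision boundaries on the reference contig
    ref_end: int
    signal_joint_offset: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)

    def signal_joint_14mer(self) -> str:
        """The 14-mer spanning the signal joint (head-to-head heptamers)."""
        return self.sequence[-7:] + self.sequence[:7]


@dataclass(frozen=True)
class TruthJunction:
    """Ground truth for one junction in a derived allele.

    Side A is the sequence that *ends at* ``pos_a``; side B *starts at*
    ``pos_b`` (0-based, half-open convention; both on the reference).
    Coordinates are canonicalized by the same left-shift rule the caller
    uses, so exact comparison is well-defined.
    """

    contig_a: str
    pos_a: int
    contig_b: str
    pos_b: int
    event_class: str
    untemplated: str = ""
    note: str = ""

    def key(self) -> Tuple[str, int, str, int]:
        return (self.contig_a, self.pos_a, self.contig_b, self.pos_b)


@dataclass(frozen=True)
class Block:
    """One reference (or untemplated) interval composing a derived allele."""

    contig: Optional[str]  # None for untemplated sequence
    ref_start: int
    ref_end: int
    allele_start: int

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class DerivedAllele:
    name: str
    sequence: str
    blocks: List[Block]
    truth: List[TruthJunction] = field(default_factory=list)
    insert_span: Optional[Tuple[str, int, int]] = None  # inserted-fragment descriptor

    def __post_init__(self):
        total = sum(b.length for b in self.blocks)
        if total != len(self.sequence):
            raise SimulationError(
                f"{self.name}: blocks cover {total} bp, sequence is {len(self.sequence)}"
            )


def reference_allele(ref: MiniReference, contig: str) -> DerivedAllele:
    """Wrap an unmodified reference contig as a (truth-free) allele."""
    seq = ref.contigs[contig]
    return DerivedAllele(f"ref_{contig}", seq, [Block(contig, 0, len(seq), 0)])


def left_shift(seq_a: str, pos_a: int, seq_b: str, pos_b: int) -> Tuple[int, int]:
    """Canonicalize a junction (A ends at pos_a, B starts at pos_b).

    While the base preceding the break on side A equals the base that
    would precede side B's start, the break can slide left one base with
    identical joined sequence; we shift to the lowest coordinates.
    """
    while pos_a > 0 and pos_b > 0 and seq_a[pos_a - 1] == seq_b[pos_b - 1]:
        pos_a -= 1
        pos_b -= 1
    return pos_a, pos_b


def _truth_junction(
    ref: MiniReference,
    contig_a: str,
    pos_a: int,
    contig_b: str,
    pos_b: int,
    event_class: str,
    untemplated: str,
    note: str = "",
) -> TruthJunction:
    if not untemplated:
        pos_a, pos_b = left_shift(
            ref.contigs[contig_a], pos_a, ref.contigs[contig_b], pos_b
        )
    return TruthJunction(contig_a, pos_a, contig_b, pos_b, event_class, untemplated, note)


# ---------------------------------------------------------------------------
# recombination
# ---------------------------------------------------------------------------

def recombine_dj(
    ref: MiniReference,
    d: SegmentAnnotation,
    j: SegmentAnnotation,
    trim: TrimParams = NO_TRIM,
    seed: int = 0,
) -> Tuple[DerivedAllele, TrecCircle]:
    """Rearrange two segments of one locus; return (coding-joint allele, circle).

    ``d`` is the upstream partner (uses its 3' RSS); ``j`` the downstream
    partner (uses its 5' RSS) and may be a D or J segment — D-D
    rearrangement (e.g. Dd2-Dd3) is the TRD case of interest.  The RSS
    spacers must satisfy the 12/23 rule.  With zero trim the coding allele
    and the circle jointly conserve every base of the locus.
    """
    rng = np.random.default_rng(seed)
    if d.kind != "D":
        raise SimulationError(f"upstream segment must be a D segment, got {d.kind}")
    if j.kind not in ("D", "J"):
        raise SimulationError(f"downstream segment must be D or J, got {j.kind}")
    if d.locus != j.locus or d.contig != j.contig:
        raise SimulationError("segments must come from the same locus")
    if d.rss_3prime is None or j.rss_5prime is None:
        raise SimulationError("required RSSs missing")
    sp_a, sp_b = d.rss_3prime.motif.spacer_len, j.rss_5prime.motif.spacer_len
    if {sp_a, sp_b} != {12, 23}:
        raise SimulationError(
            f"12/23 rule violation: spacer pairing {sp_a}/{sp_b} cannot recombine"
        )
    cut_a = d.rss_3prime.cleavage_edge
    cut_b = j.rss_5prime.cleavage_edge
    if cut_a >= cut_b:
        raise SimulationError("upstream cut must precede downstream cut")
    contig = d.contig
    seq = ref.contigs[contig]

    circle = TrecCircle(
        seq[cut_a:cut_b], (d.locus, d.name, j.name), contig, cut_a, cut_b
    )

    del_d = _sample_del(trim, rng)
    del_j = _sample_del(trim, rng)
    n_seq = _sample_n(trim, rng)
    left_end = cut_a - del_d
    right_start = cut_b + del_j
    allele_seq = seq[:left_end] + n_seq + seq[right_start:]
    blocks = [Block(contig, 0, left_end, 0)]
    if n_seq:
        blocks.append(Block(None, 0, len(n_seq), left_end))
    blocks.append(Block(contig, right_start, len(seq), left_end + len(n_seq)))
    truth = [
        _truth_junction(
            ref, contig, left_end, contig, right_start, "coding_joint", n_seq
        )
    ]
    allele = DerivedAllele(
        f"{d.locus}_{d.name}-{j.name}_coding", allele_seq, blocks, truth
    )
    return allele, circle


def insert_trec(
    ref: MiniReference,
    circle: TrecCircle,
    target: Tuple[str, int],
    noise: TrimParams = NO_TRIM,
    seed: int = 0,
) -> DerivedAllele:
    """Reinsert an excision circle at ``target``, re-opened at its signal joint.

    Re-cleavage at the signal joint regenerates the two blunt
    RSS-terminated ends, which repair into the partner break as two
    pseudo-hybrid junctions.  ``noise`` applies independent deletions and
    N-additions at each junction; a deletion of >= 8 bp on an insert end
    removes its heptamer and is flagged "RSS not identifiable".
    """
    rng = np.random.default_rng(seed)
    contig, pos = target
    if contig not in ref.contigs:
        raise SimulationError(f"unknown contig {contig!r}")
    pseq = ref.contigs[contig]
    if not (0 <= pos <= len(pseq)):
        raise SimulationError(f"insertion position {pos} outside contig {contig}")
    frag = circle.sequence  # opened exactly at the signal joint

    del_p_left = _sample_del(noise, rng)
    del_i_left = _sample_del(noise, rng)
    n_left = _sample_n(noise, rng)
    del_i_right = _sample_del(noise, rng)
    del_p_right = _sample_del(noise, rng)
    n_right = _sample_n(noise, rng)

    ins_start = circle.ref_start + del_i_left
    ins_end = circle.ref_end - del_i_right
    if ins_start >= ins_end:
        raise SimulationError("noise deleted the entire insert")
    p_left_end = pos - del_p_left
    p_right_start = pos + del_p_right

    allele_seq = (
        pseq[:p_left_end]
        + n_left
        + frag[del_i_left : len(frag) - del_i_right]
        + n_right
        + pseq[p_right_start:]
    )
    blocks = [Block(contig, 0, p_left_end, 0)]
    cursor = p_left_end
    if n_left:
        blocks.append(Block(None, 0, len(n_left), cursor))
        cursor += len(n_left)
    blocks.append(Block(circle.ref_contig, ins_start, ins_end, cursor))
    cursor += ins_end - ins_start
    if n_right:
        blocks.append(Block(None, 0, len(n_right), cursor))
        cursor += len(n_right)
    blocks.append(Block(contig, p_right_start, len(pseq), cursor))

    note_left = "RSS not identifiable" if del_i_left >= 8 else ""
    note_right = "RSS not identifiable" if del_i_right >= 8 else ""
    truth = [
        _truth_junction(
            ref, contig, p_left_end, circle.ref_contig, ins_start,
            "TREC_insertion", n_left, note_left,
        ),
        _truth_junction(
            ref, circle.ref_contig, ins_end, contig, p_right_start,
            "TREC_insertion", n_right, note_right,
        ),
    ]
    name = f"{circle.source[0]}_{circle.source[1]}-{circle.source[2]}_TREC_in_{contig}_{pos}"
    return DerivedAllele(
        name, allele_seq, blocks, truth,
        insert_span=(circle.ref_contig, ins_start, ins_end),
    )


def plant_cryptic_rss(
    ref: MiniReference, contig: str, pos: int, spacer_len: int = 12
) -> MiniReference:
    """Return a copy of ``ref`` with a consensus cryptic RSS planted so that
    its cleavage edge is exactly ``pos`` (motif extends rightward)."""
    cfg = ref.rss_config
    spacer = "T" * spacer_len  # fixed spacer; content is unscored
    text = cfg.heptamer + spacer + cfg.nonamer
    seq = ref.contigs[contig]
    if pos + len(text) > len(seq):
        raise SimulationError("cryptic RSS would run off the contig")
    new_seq = seq[:pos] + text + seq[pos + len(text):]
    contigs = dict(ref.contigs)
    contigs[contig] = new_seq
    return MiniReference(
        contigs, ref.segments, ref.partner_genes, ref.panel, ref.rss_config
    )


def make_translocation(
    ref: MiniReference,
    tr_break: Tuple[SegmentAnnotation, str],
    partner_break: Tuple[str, int],
    subtype: str,
    noise: TrimParams = NO_TRIM,
    seed: int = 0,
    cryptic_window: int = 25,
) -> Tuple[DerivedAllele, DerivedAllele]:
    """Reciprocal translocation between a TR segment break and a partner break.

    ``tr_break`` = (segment, "5p"|"3p") selects which RSS cleavage edge
    breaks.  ``subtype`` is "type1" (a cryptic RSS must already exist
    within ``cryptic_window`` of the partner break — see
    :func:`plant_cryptic_rss`) or "type2" (no such requirement; partner
    regions are screened RSS-free by construction).  If the partner break
    lies in another TR/IG locus the truth class is ``trans_rearrangement``.
    """
    from . import rss as rss_mod

    rng = np.random.default_rng(seed)
    segment, side = tr_break
    if side not in ("5p", "3p"):
        raise SimulationError("tr_break side must be '5p' or '3p'")
    rss = segment.rss_3prime if side == "3p" else segment.rss_5prime
    if rss is None:
        raise SimulationError(f"segment {segment.name} has no {side} RSS")
    cut_t = rss.cleavage_edge
    pcontig, ppos = partner_break
    if pcontig not in ref.contigs:
        raise SimulationError(f"unknown contig {pcontig!r}")
    if subtype not in ("type1", "type2"):
        raise SimulationError("subtype must be 'type1' or 'type2'")
    tr_is_partner = pcontig in ref.tr_contigs()
    if subtype == "type1" and not tr_is_partner:
        lo = max(0, ppos - cryptic_window - 32)
        hi = min(len(ref.contigs[pcontig]), ppos + cryptic_window + 32)
        hits = [
            h
            for h in rss_mod.scan_cryptic_rss(
                ref.contigs[pcontig][lo:hi], pcontig, lo, config=ref.rss_config
            )
            if abs(h.cleavage_edge - ppos) <= cryptic_window
        ]
        if not hits:
            raise SimulationError(
                "type1 translocation requires a cryptic RSS near the partner break; "
                "plant one with plant_cryptic_rss()"
            )
    event_class = "trans_rearrangement" if tr_is_partner else f"translocation_{subtype}"

    tseq = ref.contigs[segment.contig]
    pseq = ref.contigs[pcontig]

    def join(seq_a, contig_a, cut_a, seq_b, contig_b, cut_b, tag):
        del_a = _sample_del(noise, rng)
        del_b = _sample_del(noise, rng)
        n_seq = _sample_n(noise, rng)
        end_a = cut_a - del_a
        start_b = cut_b + del_b
        allele_seq = seq_a[:end_a] + n_seq + seq_b[start_b:]
        blocks = [Block(contig_a, 0, end_a, 0)]
        if n_seq:
            blocks.append(Block(None, 0, len(n_seq), end_a))
        blocks.append(Block(contig_b, start_b, len(seq_b), end_a + len(n_seq)))
        truth = [
            _truth_junction(ref, contig_a, end_a, contig_b, start_b, event_class, n_seq)
        ]
        return DerivedAllele(tag, allele_seq, blocks, truth)

    base = f"{segment.locus}_{segment.name}_{subtype}_{pcontig}_{ppos}"
    if side == "3p":
        der1 = join(tseq, segment.contig, cut_t, pseq, pcontig, ppos, base + "_der1")
        der2 = join(pseq, pcontig, ppos, tseq, segment.contig, cut_t, base + "_der2")
    else:
        der1 = join(pseq, pcontig, ppos, tseq, segment.contig, cut_t, base + "_der1")
        der2 = join(tseq, segment.contig, cut_t, pseq, pcontig, ppos, base + "_der2")
    return der1, der2


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadPair:
    name: str
    seq1: str
    seq2: str


def _panel_by_contig(panel) -> Dict[str, List[Tuple[int, int]]]:
    d: Dict[str, List[Tuple[int, int]]] = {}
    for c, s, e in panel:
        d.setdefault(c, []).append((s, e))
    return d


def _fragment_on_panel(
    allele: DerivedAllele, fs: int, fe: int, panel: Dict[str, List[Tuple[int, int]]]
) -> bool:
    for b in allele.blocks:
        if b.contig is None:
            continue
        a_lo = b.allele_start
        a_hi = b.allele_start + b.length
        lo = max(fs, a_lo)
        hi = min(fe, a_hi)
        if lo >= hi:
            continue
        r_lo = b.ref_start + (lo - a_lo)
        r_hi = b.ref_start + (hi - a_lo)
        for ps, pe in panel.get(b.contig, ()):
            if ps < r_hi and r_lo < pe:
                return True
    return False


def _add_errors(seq: str, err_rate: float, rng: np.random.Generator) -> str:
    if err_rate <= 0:
        return seq
    n = len(seq)
    mask = rng.random(n) < err_rate
    if not mask.any():
        return seq
    chars = list(seq)
    for i in np.nonzero(mask)[0]:
        old = chars[i]
        choices = [b for b in BASES if b != old]
        chars[i] = choices[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_reads(
    alleles: Sequence[DerivedAllele],
    panel: Sequence[Tuple[str, int, int]],
    coverage: float = 100.0,
    read_len: int = 150,
    frag_mean: float = 350.0,
    frag_sd: float = 50.0,
    err_rate: float = 0.0,
    seed: int = 0,
) -> List[ReadPair]:
    """Emit captured paired-end reads from a set of alleles.

    ``coverage`` is the pre-capture depth over each allele; fragments are
    retained only if they project (through the allele's block structure)
    onto a panel interval.  Read names encode the source allele and the
    fragment's allele coordinates, providing a truth channel.
    Deterministic per seed.
    """
    if coverage <= 0:
        raise SimulationError("coverage must be > 0")
    if read_len < 50:
        raise SimulationError("read_len must be >= 50")
    rng = np.random.default_rng(seed)
    panel_d = _panel_by_contig(panel)
    pairs: List[ReadPair] = []
    for allele in alleles:
        L = len(allele.sequence)
        if L < read_len:
            continue
        n_frags = int(math.ceil(coverage * L / (2.0 * read_len)))
        sizes = rng.normal(frag_mean, frag_sd, n_frags)
        starts = rng.random(n_frags)
        for i in range(n_frags):
            flen = max(read_len, int(round(sizes[i])))
            flen = min(flen, L)
            fs = int(starts[i] * (L - flen + 1))
            fe = fs + flen
            if not _fragment_on_panel(allele, fs, fe, panel_d):
                continue
            frag = allele.sequence[fs:fe]
            r1 = _add_errors(frag[:read_len], err_rate, rng)
            r2 = _add_errors(revcomp(frag)[:read_len], err_rate, rng)
            pairs.append(ReadPair(f"{allele.name}|{fs}|{fe}|{i}", r1, r2))
    return pairs


def write_fastq_pair(pairs: Sequence[ReadPair], path1, path2, qual_char: str = "I") -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{qual_char * len(p.seq1)}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{qual_char * len(p.seq2)}\n")


def read_fastq_pair(path1, path2) -> List[ReadPair]:
    from Bio import SeqIO

    reads1 = list(SeqIO.parse(str(path1), "fastq"))
    reads2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(reads1) != len(reads2):
        raise SimulationError("FASTQ mates differ in read count")
    pairs = []
    for r1, r2 in zip(reads1, reads2):
        name = r1.id
        if name.endswith("/1"):
            name = name[:-2]
        pairs.append(ReadPair(name, str(r1.seq).upper(), str(r2.seq).upper()))
    return pairs


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSample:
    sample_id: str
    alleles: List[DerivedAllele]
    event_class: str
    partner_gene: str
    truth_junctions: List[TruthJunction]
    pairs: List[ReadPair] = field(default_factory=list)


def default_cryptic_sites(ref: MiniReference, per_gene: int = 4) -> List[Tuple[str, int]]:
    """Deterministic germline cryptic-RSS positions inside partner genes."""
    sites = []
    for p in ref.partner_genes:
        span = p.end - p.start
        for i in range(per_gene):
            sites.append((p.contig, p.start + (i + 1) * span // (per_gene + 1)))
    return sites


def simulate_cohort(
    ref: MiniReference,
    n_per_class: int = 20,
    noise: TrimParams = DEFAULT_TRIM,
    coverage: float = 100.0,
    read_len: int = 150,
    err_rate: float = 0.002,
    seed: int = 0,
    include_background: bool = True,
) -> Tuple[MiniReference, List[SimulatedSample]]:
    """Simulate a cohort with ``n_per_class`` samples of each event type.

    Event types: TRD Dd2-Dd3 TREC insertion, TRB Db2-Jb2-3 TREC insertion,
    type-1 translocation (cryptic RSS pre-planted in the germline of the
    returned reference copy), type-2 translocation into screened partner
    sequence, and TRD-TRG trans-rearrangement.  Returns the (possibly
    modified) reference to map against, and one sample per event.
    """
    rng = np.random.default_rng(seed)
    cryptic_sites = default_cryptic_sites(ref)
    for contig, pos in cryptic_sites:
        ref = plant_cryptic_rss(ref, contig, pos)

    dd2 = ref.segment("TRD", "Dd2")
    dd3 = ref.segment("TRD", "Dd3")
    db2 = ref.segment("TRB", "Db2")
    jb23 = ref.segment("TRB", "Jb2-3")
    jg1 = ref.segment("TRG", "Jg1")
    _, trd_circle = recombine_dj(ref, dd2, dd3, NO_TRIM, seed=int(rng.integers(2**31)))
    _, trb_circle = recombine_dj(ref, db2, jb23, NO_TRIM, seed=int(rng.integers(2**31)))

    partners = [p for p in ref.partner_genes if p.name != "mtDNA"]

    def rand_pos_in(p, margin=500):
        return int(rng.integers(p.start + margin, p.end - margin))

    def near_cryptic(margin=400):
        # type-2 positions keep away from the planted cryptic sites
        while True:
            p = partners[int(rng.integers(len(partners)))]
            pos = rand_pos_in(p)
            if all(
                c != p.contig or abs(pos - s) > margin for c, s in cryptic_sites
            ):
                return p, pos

    samples: List[SimulatedSample] = []
    idx = 0
    for cls_i in range(n_per_class):
        for kind in ("trec_trd", "trec_trb", "type1", "type2", "trans"):
            idx += 1
            sid = f"S{idx:04d}"
            sub_seed = int(rng.integers(2**31))
            if kind in ("trec_trd", "trec_trb"):
                circle = trd_circle if kind == "trec_trd" else trb_circle
                p = partners[int(rng.integers(len(partners)))]
                pos = rand_pos_in(p)
                allele = insert_trec(ref, circle, (p.contig, pos), noise, sub_seed)
                alleles = [allele]
                cls, partner = "TREC_insertion", p.name
            elif kind == "type1":
                contig, pos = cryptic_sites[int(rng.integers(len(cryptic_sites)))]
                p = ref.partner_at(contig, pos)
                der1, der2 = make_translocation(
                    ref, (dd2, "3p"), (contig, pos), "type1", noise, sub_seed
                )
                alleles = [der1, der2]
                cls, partner = "translocation_type1", p.name if p else "unknown"
            elif kind == "type2":
                p, pos = near_cryptic()
                der1, der2 = make_translocation(
                    ref, (dd2, "3p"), (p.contig, pos), "type2", noise, sub_seed
                )
                alleles = [der1, der2]
                cls, partner = "translocation_type2", p.name
            else:
                der1, der2 = make_translocation(
                    ref, (dd2, "3p"), ("TRG", jg1.rss_5prime.cleavage_edge),
                    "type2", noise, sub_seed,
                )
                alleles = [der1, der2]
                cls, partner = "trans_rearrangement", "TRG"
            truth = [t for a in alleles for t in a.truth]
            sim_alleles = list(alleles)
            if include_background:
                bg = {b.contig for a in alleles for b in a.blocks if b.contig}
                sim_alleles += [reference_allele(ref, c) for c in sorted(bg)]
            pairs = simulate_reads(
                sim_alleles, ref.panel, coverage, read_len,
                err_rate=err_rate, seed=int(rng.integers(2**31)),
            )
            samples.append(SimulatedSample(sid, alleles, cls, partner, truth, pairs))
    return ref, samples


def truth_table(samples: Sequence[SimulatedSample]):
    """Ground-truth junction table as a DataFrame (one row per junction)."""
    import pandas as pd

    rows = []
    for s in samples:
        for t in s.truth_junctions:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "event_class": s.event_class,
                    "partner_gene": s.partner_gene,
                    "contig_a": t.contig_a,
                    "pos_a": t.pos_a,
                    "contig_b": t.contig_b,
                    "pos_b": t.pos_b,
                    "untemplated": t.untemplated,
                    "note": t.note,
                }
            )
    return pd.DataFrame(rows)
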