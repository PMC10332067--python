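"""Recombination signal sequence (RSS) motif scoring and breakpoint-end annotation.

An RSS is a conserved heptamer and nonamer separated by a 12 or 23 nt
spacer; RAG cleaves precisely between the heptamer and the adjacent gene
segment.  Authentic RSSs flank the annotated V/D/J segments; RSS-like
motifs elsewhere in the genome ("cryptic" RSSs) can be illegitimately
targeted, which distinguishes type 1 from type 2 translocations.

Scoring is a weighted identity to the consensus: the heptamer contributes
``W_HEPTAMER`` of the score with its first three bases (the functionally
critical CAC) counted twice, the nonamer contributes ``W_NONAMER`` with
uniform base weights.  A perfect heptamer + nonamer scores 1.0 regardless
of spacer content; cryptic hits tolerate spacers of 12 +/- 1 or 23 +/- 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

HEPTAMER_CONSENSUS = "CACAGTG"
NONAMER_CONSENSUS = "ACAAAAACC"
W_HEPTAMER = 0.7
W_NONAMER = 0.3
#: heptamer per-position weights: CAC core double-weighted
HEPTAMER_WEIGHTS = np.array([2.0, 2.0, 2.0, 1.0, 1.0, 1.0, 1.0])
CRYPTIC_SPACERS = (11, 12, 13, 22, 23, 24)
DEFAULT_CRYPTIC_THRESHOLD = 0.80
DEFAULT_BREAK_WINDOW = 25

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse-complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RssHit:
    """One RSS-like motif placement on a contig.

    ``heptamer_start`` is the 0-based plus-strand coordinate of the first
    heptamer base.  On the minus strand the motif reads
    heptamer..spacer..nonamer right-to-left; ``heptamer_start`` still
    addresses the plus-strand position of the heptamer's leftmost base.
    """

    contig: str
    heptamer_start: int
    spacer_len: int
    score: float
    strand: str
    kind: str  # "authentic" | "cryptic"

    @property
    def cleavage_edge(self) -> int:
        """Plus-strand coordinate of the RAG cut site (blunt signal end).

        RAG cuts between the heptamer and the gene segment.  For a
        plus-strand motif the segment sits 5' of the heptamer, so the cut
        is at ``heptamer_start``; for a minus-strand motif it is at the
        heptamer's right edge.
        """
        if self.strand == "+":
            return self.heptamer_start
        return self.heptamer_start + 7


@dataclass(frozen=True)
class EndAnnotation:
    """Classification of one junction end: authentic SE, cryptic RSS, or none."""

    contig: str
    pos: int
    category: str  # "authentic_signal_end" | "cryptic_rss" | "none"
    best_hit: Optional[RssHit]
    distance_to_break: Optional[int]


class RssConfig:
    """Scoring configuration (consensus strings, weights, threshold)."""

    def __init__(
        self,
        heptamer: str = HEPTAMER_CONSENSUS,
        nonamer: str = NONAMER_CONSENSUS,
        w_heptamer: float = W_HEPTAMER,
        w_nonamer: float = W_NONAMER,
        threshold: float = DEFAULT_CRYPTIC_THRESHOLD,
    ):
        if len(heptamer) != 7 or len(nonamer) != 9:
            raise ValueError("heptamer must be 7 nt and nonamer 9 nt")
        self.heptamer = heptamer.upper()
        self.nonamer = nonamer.upper()
        self.w_heptamer = w_heptamer
        self.w_nonamer = w_nonamer
        self.threshold = threshold


DEFAULT_CONFIG = RssConfig()


def score_rss(
    seq: str,
    offset: int,
    spacer_len: int,
    config: RssConfig = DEFAULT_CONFIG,
) -> float:
    """Score the RSS whose heptamer starts at ``offset`` in ``seq``.

    The motif occupies ``offset .. offset + 16 + spacer_len`` (heptamer,
    spacer, nonamer, 5'->3' in motif orientation).  Returns the weighted
    identity in [0, 1].

    Raises ``ValueError`` if the window does not fit.
    """
    need = offset + 7 + spacer_len + 9
    if offset < 0 or need > len(seq):
        raise ValueError(
            f"window too short: need {need} bases from offset {offset}, have {len(seq)}"
        )
    hept = seq[offset : offset + 7].upper()
    non = seq[offset + 7 + spacer_len : offset + 16 + spacer_len].upper()
    wsum = HEPTAMER_WEIGHTS.sum()
    h_id = sum(
        w for w, a, b in zip(HEPTAMER_WEIGHTS, hept, config.heptamer) if a == b
    ) / wsum
    n_id = sum(1 for a, b in zip(non, config.nonamer) if a == b) / 9.0
    return config.w_heptamer * h_id + config.w_nonamer * n_id


_BASE_CODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_plus(
    codes: np.ndarray, config: RssConfig, spacers: Sequence[int]
) -> list[tuple[int, int, float]]:
    """Vectorized plus-orientation scan; returns (offset, spacer, score)."""
    out: list[tuple[int, int, float]] = []
    hcons = _encode(config.heptamer)
    ncons = _encode(config.nonamer)
    wsum = HEPTAMER_WEIGHTS.sum()
    n = len(codes)
    for spacer in spacers:
        motif_len = 16 + spacer
        if n < motif_len:
            continue
        m = n - motif_len + 1
        hs = np.zeros(m)
        for j in range(7):
            hs += HEPTAMER_WEIGHTS[j] * (codes[j : j + m] == hcons[j])
        ns = np.zeros(m)
        for j in range(9):
            k = 7 + spacer + j
            ns += codes[k : k + m] == ncons[j]
        scores = config.w_heptamer * hs / wsum + config.w_nonamer * ns / 9.0
        idx = np.nonzero(scores >= config.threshold)[0]
        for i in idx:
            out.append((int(i), spacer, float(scores[i])))
    return out


def scan_cryptic_rss(
    seq: str,
    contig: str = "",
    start: int = 0,
    threshold: Optional[float] = None,
    config: RssConfig = DEFAULT_CONFIG,
    spacers: Sequence[int] = CRYPTIC_SPACERS,
) -> list[RssHit]:
    """Exhaustively scan ``seq`` (both strands, all cryptic spacer lengths).

    ``start`` offsets reported coordinates so a sub-interval of a contig can
    be scanned in place.  Hits are sorted by score descending, then
    coordinate.  Equivalent to brute-force enumeration of every window.
    """
    if threshold is not None and threshold != config.threshold:
        config = RssConfig(
            config.heptamer, config.nonamer, config.w_heptamer, config.w_nonamer, threshold
        )
    hits: list[RssHit] = []
    codes = _encode(seq)
    for off, spacer, score in _scan_plus(codes, config, spacers):
        hits.append(RssHit(contig, start + off, spacer, score, "+", "cryptic"))
    rc_codes = _encode(revcomp(seq))
    n = len(seq)
    for off, spacer, score in _scan_plus(rc_codes, config, spacers):
        # minus-strand motif: heptamer occupies plus-strand
        # [n - off - 7, n - off) relative to seq
        plus_start = n - off - 7
        hits.append(RssHit(contig, start + plus_start, spacer, score, "-", "cryptic"))
    hits.sort(key=lambda h: (-h.score, h.heptamer_start, h.strand, h.spacer_len))
    return hits


def annotate_breakpoint_end(
    contig: str,
    pos: int,
    ref,
    window: int = DEFAULT_BREAK_WINDOW,
    config: RssConfig = DEFAULT_CONFIG,
) -> EndAnnotation:
    """Classify a breakpoint end against annotated and cryptic RSSs.

    ``ref`` is a :class:`treccap.reference.MiniReference`.  Decision order:

    1. ``authentic_signal_end`` if ``pos`` coincides exactly with the RAG
       cleavage edge of an annotated RSS on this contig;
    2. ``cryptic_rss`` if a scan of ``[pos - window, pos + window]`` yields a
       hit whose cleavage edge lies within ``window`` of ``pos``;
    3. ``none`` otherwise.
    """
    for seg in ref.segments:
        if seg.contig != contig:
            continue
        for hit in seg.rss_hits():
            if hit.cleavage_edge == pos:
                return EndAnnotation(contig, pos, "authentic_signal_end", hit, 0)
    seq = ref.contigs[contig]
    # scan wide enough that a motif whose cleavage edge is within `window`
    # fits entirely inside the scanned interval (longest motif = 7+24+9)
    pad = window + 40
    lo = max(0, pos - pad)
    hi = min(len(seq), pos + pad)
    hits = [
        h
        for h in scan_cryptic_rss(seq[lo:hi], contig, lo, config=config)
        if abs(h.cleavage_edge - pos) <= window
    ]
    if hits:
        best = hits[0]
        return EndAnnotation(
            contig, pos, "cryptic_rss", best, abs(best.cleavage_edge - pos)
        )
    return EndAnnotation(contig, pos, "none", None, None)


def hits_to_bed(hits: Sequence[RssHit]) -> str:
    """Render hits as BED6 lines (score scaled 0-1000)."""
    lines = []
    for h in hits:
        end = h.heptamer_start + 16 + h.spacer_len if h.strand == "+" else h.heptamer_start + 7
        start = h.heptamer_start if h.strand == "+" else h.heptamer_start + 7 - (16 + h.spacer_len)
        name = f"RSS_{h.kind}_{h.spacer_len}"
        lines.append(
            f"{h.contig}\t{start}\t{end}\t{name}\t{int(round(h.score * 1000))}\t{h.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
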