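"""Miniature reference model for TR loci, partner genes and capture panel.

The package operates on a desk-scale surrogate genome: one contig per
antigen-receptor locus (TRD, TRB, TRG, IGH) carrying annotated D/J gene
segments with their flanking RSSs, plus partner-gene contigs (a ZFP36L2
surrogate region, a second partner region, and an mtDNA-sized contig).
Coordinates are 0-based half-open throughout; BED output is standard BED.

Locus geometry is configurable.  The defaults place the Dd2/Dd3 excision
boundaries 10,000 bp apart and the Db2/Jb2-3 boundaries 1,200 bp apart, so
the full excision circles produced by the simulator have those lengths.

Background sequence is random with uniform base composition from the
config seed and is screened so that no window scores at or above the
cryptic-RSS threshold except the planted, annotated RSSs — making
"RSS-free partner break" test cases constructible by design.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import rss as rss_mod
from .rss import RssConfig, RssHit, revcomp

TR_LOCI = ("TRD", "TRB", "TRG", "IGH")
BASES = np.array(list("ACGT"))


class ReferenceError(ValueError):
    """Configuration or validation failure while building/loading a reference."""


@dataclass(frozen=True)
class RSSMotif:
    """An RSS motif: heptamer, 12/23 spacer, nonamer.

    ``orientation`` gives the direction of the recombination-competent face
    relative to the contig plus strand: ``points_downstream`` motifs read
    heptamer->nonamer left-to-right (plus strand), ``points_upstream``
    motifs read right-to-left (reverse complement on the plus strand).
    """

    heptamer: str
    spacer_len: int
    nonamer: str
    orientation: str

    def __post_init__(self):
        if len(self.heptamer) != 7:
            raise ReferenceError(f"heptamer length != 7: {self.heptamer!r}")
        if len(self.nonamer) != 9:
            raise ReferenceError(f"nonamer length != 9: {self.nonamer!r}")
        for s in (self.heptamer, self.nonamer):
            if set(s.upper()) - set("ACGT"):
                raise ReferenceError(f"invalid DNA alphabet in {s!r}")
        if self.spacer_len not in (12, 23):
            raise ReferenceError(f"authentic RSS spacer must be 12 or 23, got {self.spacer_len}")
        if self.orientation not in ("points_downstream", "points_upstream"):
            raise ReferenceError(f"bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class AnnotatedRSS:
    """An RSSMotif placed on a contig, attached to one side of a segment."""

    motif: RSSMotif
    contig: str
    start: int  # plus-strand interval of the whole motif (hept+spacer+nonamer)
    end: int

    @property
    def strand(self) -> str:
        return "+" if self.motif.orientation == "points_downstream" else "-"

    @property
    def heptamer_interval(self) -> Tuple[int, int]:
        if self.strand == "+":
            return (self.start, self.start + 7)
        return (self.end - 7, self.end)

    @property
    def cleavage_edge(self) -> int:
        """RAG cut site: the heptamer edge abutting the gene segment."""
        hs, he = self.heptamer_interval
        return hs if self.strand == "+" else he

    def to_hit(self) -> RssHit:
        hs, _ = self.heptamer_interval
        return RssHit(self.contig, hs, self.motif.spacer_len, 1.0, self.strand, "authentic")


@dataclass(frozen=True)
class SegmentAnnotation:
    """A V/D/J gene segment with coordinates and flanking RSS annotations."""

    locus: str
    name: str
    kind: str  # V | D | J
    contig: str
    start: int
    end: int
    strand: str = "+"
    rss_5prime: Optional[AnnotatedRSS] = None
    rss_3prime: Optional[AnnotatedRSS] = None

    def __post_init__(self):
        if self.locus not in TR_LOCI:
            raise ReferenceError(f"unknown locus {self.locus!r}")
        if self.kind not in ("V", "D", "J"):
            raise ReferenceError(f"segment kind must be V/D/J, got {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ReferenceError(f"bad segment interval [{self.start},{self.end})")
        if self.kind == "D" and (self.rss_5prime is None or self.rss_3prime is None):
            raise ReferenceError(f"D segment {self.name} must carry 5' and 3' RSSs")
        if self.kind == "J" and self.rss_5prime is None:
            raise ReferenceError(f"J segment {self.name} must carry a 5' RSS")

    def rss_hits(self) -> List[RssHit]:
        return [r.to_hit() for r in (self.rss_5prime, self.rss_3prime) if r is not None]


@dataclass(frozen=True)
class PartnerGene:
    name: str
    contig: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class MiniReference:
    """Contigs, segment annotations, partner genes, and capture panel."""

    contigs: Dict[str, str]
    segments: List[SegmentAnnotation]
    partner_genes: List[PartnerGene]
    panel: List[Tuple[str, int, int]]
    rss_config: RssConfig = field(default_factory=RssConfig)

    def validate(self) -> None:
        errors = []
        for seg in self.segments:
            if seg.contig not in self.contigs:
                errors.append(f"segment {seg.name}: contig {seg.contig} missing")
                continue
            if seg.end > len(self.contigs[seg.contig]):
                errors.append(f"segment {seg.name}: interval exceeds contig")
            for r in (seg.rss_5prime, seg.rss_3prime):
                if r and not (0 <= r.start < r.end <= len(self.contigs[r.contig])):
                    errors.append(f"RSS of {seg.name}: interval outside contig")
        names = [p.name for p in self.partner_genes]
        if len(set(names)) != len(names):
            errors.append("partner-gene names not unique")
        for locus in TR_LOCI:
            segnames = [s.name for s in self.segments if s.locus == locus]
            if len(set(segnames)) != len(segnames):
                errors.append(f"duplicate segment names in {locus}")
        for p in self.partner_genes:
            if p.contig not in self.contigs or p.end > len(self.contigs[p.contig]):
                errors.append(f"partner {p.name}: bad interval")
        for c, s, e in self.panel:
            if c not in self.contigs or not (0 <= s < e <= len(self.contigs[c])):
                errors.append(f"panel interval {c}:{s}-{e} invalid")
        if errors:
            raise ReferenceError("reference validation failed:\n  " + "\n  ".join(errors))

    # -- lookup helpers -------------------------------------------------

    def segment(self, locus: str, name: str) -> SegmentAnnotation:
        for s in self.segments:
            if s.locus == locus and s.name == name:
                return s
        raise KeyError(f"{locus}/{name}")

    def tr_contigs(self) -> Dict[str, str]:
        """Map contig -> locus for contigs that carry TR/IG segments."""
        return {s.contig: s.locus for s in self.segments}

    def partner_at(self, contig: str, pos: int) -> Optional[PartnerGene]:
        for p in self.partner_genes:
            if p.contig == contig and p.start <= pos < p.end:
                return p
        return None

    def excision_boundaries(
        self, locus: str, upstream: str, downstream: str
    ) -> Tuple[int, int]:
        """Cut sites of a rearrangement: (3'RSS edge of upstream segment,
        5'RSS edge of downstream segment); their distance is the circle size."""
        a = self.segment(locus, upstream)
        b = self.segment(locus, downstream)
        if a.rss_3prime is None or b.rss_5prime is None:
            raise ReferenceError("segments lack the RSSs required for excision")
        return a.rss_3prime.cleavage_edge, b.rss_5prime.cleavage_edge


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

@dataclass
class ReferenceConfig:
    """Tunable geometry of the surrogate genome.

    ``dd2_dd3_distance`` / ``db2_jb23_distance`` are the excision-boundary
    distances that become the full TREC circle sizes (defaults 10,000 bp
    and 1,200 bp).
    """

    seed: int = 0
    dd2_dd3_distance: int = 10_000
    db2_jb23_distance: int = 1_200
    contig_lengths: Dict[str, int] = field(
        default_factory=lambda: {
            "TRD": 30_000,
            "TRB": 20_000,
            "TRG": 20_000,
            "IGH": 20_000,
            "ZFP36L2_region": 20_000,
            "MORN3_region": 12_000,
            "mtDNA": 16_500,
        }
    )
    heptamer: str = rss_mod.HEPTAMER_CONSENSUS
    nonamer: str = rss_mod.NONAMER_CONSENSUS
    cryptic_threshold: float = rss_mod.DEFAULT_CRYPTIC_THRESHOLD
    panel_flank: int = 300

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ReferenceConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)


#: (locus, name, kind, start, seg_len, spacer_5p, spacer_3p); None = no RSS.
#: Dd3/Jb2-3 starts are overridden from the configured excision distances.
_SEGMENT_PLAN = [
    ("TRD", "Dd2", "D", 4_000, 9, 12, 23),
    ("TRD", "Dd3", "D", None, 13, 12, 23),   # start set from dd2_dd3_distance
    ("TRB", "Db2", "D", 3_000, 12, 12, 23),
    ("TRB", "Jb2-3", "J", None, 48, 12, None),  # start set from db2_jb23_distance
    ("TRG", "Jg1", "J", 5_000, 50, 12, None),
    ("IGH", "Jh4", "J", 5_000, 50, 23, None),
]

_PARTNER_PLAN = [
    ("ZFP36L2", "ZFP36L2_region", 5_000, 15_000),
    ("MORN3", "MORN3_region", 3_000, 9_000),
    ("mtDNA", "mtDNA", 0, 16_500),
]


def _random_spacer(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def build_mini_reference(config: Optional[ReferenceConfig] = None) -> MiniReference:
    """Build the surrogate reference deterministically from a config.

    Background sequence is seeded random DNA, screened (after planting the
    annotated RSSs) so that no unplanted window reaches the cryptic-RSS
    score threshold.
    """
    config = config or ReferenceConfig()
    if config.dd2_dd3_distance <= 0 or config.db2_jb23_distance <= 0:
        raise ReferenceError("excision distances must be positive")
    rng = np.random.default_rng(config.seed)
    rss_config = RssConfig(
        config.heptamer, config.nonamer, threshold=config.cryptic_threshold
    )

    seqs = {
        name: list("".join(BASES[rng.integers(0, 4, length)]))
        for name, length in config.contig_lengths.items()
    }

    # resolve geometry-dependent starts
    plan = []
    dd2_cut = None
    db2_cut = None
    for locus, name, kind, start, seg_len, sp5, sp3 in _SEGMENT_PLAN:
        if name == "Dd3":
            assert dd2_cut is not None
            start = dd2_cut + config.dd2_dd3_distance
        elif name == "Jb2-3":
            assert db2_cut is not None
            start = db2_cut + config.db2_jb23_distance
        end = start + seg_len
        if name == "Dd2":
            dd2_cut = end  # 3'RSS cleavage edge abuts segment end
        elif name == "Db2":
            db2_cut = end
        plan.append((locus, name, kind, start, end, sp5, sp3))

    segments: List[SegmentAnnotation] = []
    protected: Dict[str, List[Tuple[int, int]]] = {c: [] for c in seqs}
    for locus, name, kind, start, end, sp5, sp3 in plan:
        contig = locus
        if end > len(seqs[contig]):
            raise ReferenceError(f"segment {name} exceeds contig {contig}")
        rss5 = rss3 = None
        if sp5 is not None:
            motif = RSSMotif(config.heptamer, sp5, config.nonamer, "points_upstream")
            spacer = _random_spacer(rng, sp5)
            text = revcomp(config.heptamer + spacer + config.nonamer)
            mstart = start - len(text)
            if mstart < 0:
                raise ReferenceError(f"5' RSS of {name} runs off contig start")
            seqs[contig][mstart:start] = list(text)
            rss5 = AnnotatedRSS(motif, contig, mstart, start)
            protected[contig].append((mstart, start))
        if sp3 is not None:
            motif = RSSMotif(config.heptamer, sp3, config.nonamer, "points_downstream")
            spacer = _random_spacer(rng, sp3)
            text = config.heptamer + spacer + config.nonamer
            mend = end + len(text)
            if mend > len(seqs[contig]):
                raise ReferenceError(f"3' RSS of {name} runs off contig end")
            seqs[contig][end:mend] = list(text)
            rss3 = AnnotatedRSS(motif, contig, end, mend)
            protected[contig].append((end, mend))
        segments.append(
            SegmentAnnotation(locus, name, kind, contig, start, end, "+", rss5, rss3)
        )

    _screen_background(seqs, protected, rng, rss_config)

    partner_genes = [PartnerGene(*p) for p in _PARTNER_PLAN if p[1] in seqs]
    flank = config.panel_flank
    panel = []
    for seg in segments:
        lo = seg.rss_5prime.start if seg.rss_5prime else seg.start
        hi = seg.rss_3prime.end if seg.rss_3prime else seg.end
        panel.append(
            (seg.contig, max(0, lo - flank), min(len(seqs[seg.contig]), hi + flank))
        )
    panel = _merge_intervals(panel)

    ref = MiniReference(
        {c: "".join(s) for c, s in seqs.items()},
        segments,
        partner_genes,
        panel,
        rss_config,
    )
    ref.validate()
    return ref


def _merge_intervals(ivs: List[Tuple[str, int, int]]) -> List[Tuple[str, int, int]]:
    out: List[Tuple[str, int, int]] = []
    for c, s, e in sorted(ivs):
        if out and out[-1][0] == c and s <= out[-1][2]:
            out[-1] = (c, out[-1][1], max(e, out[-1][2]))
        else:
            out.append((c, s, e))
    return out


def _screen_background(
    seqs: Dict[str, List[str]],
    protected: Dict[str, List[Tuple[int, int]]],
    rng: np.random.Generator,
    rss_config: RssConfig,
    max_passes: int = 12,
) -> None:
    """Mutate background bases until no unplanted window reaches the
    cryptic threshold.  Windows overlapping planted RSSs are left alone."""

    def is_protected(contig: str, lo: int, hi: int) -> bool:
        return any(s < hi and lo < e for s, e in protected[contig])

    for contig, seq in seqs.items():
        for _ in range(max_passes):
            hits = rss_mod.scan_cryptic_rss("".join(seq), contig, config=rss_config)
            dirty = []
            for h in hits:
                motif_len = 16 + h.spacer_len
                lo = h.heptamer_start if h.strand == "+" else h.heptamer_start + 7 - motif_len
                if not is_protected(contig, lo, lo + motif_len):
                    dirty.append(h)
            if not dirty:
                break
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            for h in dirty:
                # break the double-weighted CAC core (motif positions 1-2)
                for j in (1, 2):
                    pos = h.heptamer_start + (j if h.strand == "+" else 6 - j)
                    motif_j = j if h.strand == "+" else j  # motif position
                    cons = rss_config.heptamer[motif_j]
                    if h.strand == "-":
                        cons = comp[cons]
                    old = seq[pos]
                    choices = [b for b in "ACGT" if b != old and b != cons]
                    seq[pos] = choices[int(rng.integers(0, len(choices)))]
        else:
            raise ReferenceError(f"could not screen contig {contig} of cryptic RSS hits")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_reference(ref: MiniReference, outdir) -> Dict[str, Path]:
    """Write FASTA + BED files; returns the paths written.

    ``segments.bed`` encodes segments and their RSSs in the name field
    (``locus;name;seg;kind`` and ``locus;name;rss5/rss3;spacer``), so the
    annotation round-trips losslessly through ``load_reference``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "reference.fasta",
        "segments": outdir / "segments.bed",
        "partners": outdir / "partners.bed",
        "panel": outdir / "panel.bed",
    }
    with open(paths["fasta"], "w") as fh:
        for name in sorted(ref.contigs):
            fh.write(f">{name}\n")
            seq = ref.contigs[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(paths["segments"], "w") as fh:
        for seg in ref.segments:
            fh.write(
                f"{seg.contig}\t{seg.start}\t{seg.end}\t"
                f"{seg.locus};{seg.name};seg;{seg.kind}\t0\t{seg.strand}\n"
            )
            for side, r in (("rss5", seg.rss_5prime), ("rss3", seg.rss_3prime)):
                if r is not None:
                    fh.write(
                        f"{r.contig}\t{r.start}\t{r.end}\t"
                        f"{seg.locus};{seg.name};{side};{r.motif.spacer_len}\t0\t{r.strand}\n"
                    )
    with open(paths["partners"], "w") as fh:
        for p in ref.partner_genes:
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\t{p.name}\t0\t{p.strand}\n")
    with open(paths["panel"], "w") as fh:
        for c, s, e in ref.panel:
            fh.write(f"{c}\t{s}\t{e}\tpanel\n")
    return paths


def _read_bed(path) -> List[List[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            rows.append(line.split("\t"))
    return rows


def load_reference(
    fasta_path,
    segments_bed,
    partners_bed=None,
    panel_bed=None,
    rss_config: Optional[RssConfig] = None,
) -> MiniReference:
    """Load a reference written by :func:`write_reference`.

    Raises :class:`ReferenceError` listing every malformed BED record
    (end <= start, unknown contig, interval outside contig).
    """
    from Bio import SeqIO

    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    errors = []

    def check(contig, start, end, what) -> bool:
        if contig not in contigs:
            errors.append(f"{what}: unknown contig {contig!r}")
            return False
        if not start < end:
            errors.append(f"{what}: end <= start ({start},{end})")
            return False
        if start < 0 or end > len(contigs[contig]):
            errors.append(f"{what}: interval outside contig {contig}")
            return False
        return True

    seg_rows: Dict[Tuple[str, str], dict] = {}
    for row in _read_bed(segments_bed):
        contig, start, end, name = row[0], int(row[1]), int(row[2]), row[3]
        strand = row[5] if len(row) > 5 else "+"
        if not check(contig, start, end, f"segments.bed {name}"):
            continue
        parts = name.split(";")
        if len(parts) != 4:
            errors.append(f"segments.bed: bad name field {name!r}")
            continue
        locus, segname, rectype, extra = parts
        entry = seg_rows.setdefault((locus, segname), {})
        if rectype == "seg":
            entry["seg"] = (contig, start, end, extra, strand)
        else:
            entry[rectype] = (contig, start, end, int(extra), strand)
    if errors:
        raise ReferenceError("BED validation failed:\n  " + "\n  ".join(errors))

    segments = []
    for (locus, segname), entry in seg_rows.items():
        if "seg" not in entry:
            errors.append(f"segment {locus}/{segname}: RSS rows without a seg row")
            continue
        contig, start, end, kind, strand = entry["seg"]

        def mk_rss(key, orientation):
            if key not in entry:
                return None
            c, s, e, spacer, st = entry[key]
            hs, he = (s, s + 7) if st == "+" else (e - 7, e)
            hept = contigs[c][hs:he]
            if st == "-":
                hept = revcomp(hept)
            ns, ne = (e - 9, e) if st == "+" else (s, s + 9)
            non = contigs[c][ns:ne]
            if st == "-":
                non = revcomp(non)
            motif = RSSMotif(hept, spacer, non, orientation)
            return AnnotatedRSS(motif, c, s, e)

        # a 5' RSS of a plus-strand segment points upstream, a 3' downstream
        segments.append(
            SegmentAnnotation(
                locus, segname, kind, contig, start, end, strand,
                mk_rss("rss5", "points_upstream"),
                mk_rss("rss3", "points_downstream"),
            )
        )

    partner_genes = []
    if partners_bed is not None:
        for row in _read_bed(partners_bed):
            contig, start, end, name = row[0], int(row[1]), int(row[2]), row[3]
            strand = row[5] if len(row) > 5 else "+"
            if check(contig, start, end, f"partners.bed {name}"):
                partner_genes.append(PartnerGene(name, contig, start, end, strand))

    panel = []
    if panel_bed is not None:
        for row in _read_bed(panel_bed):
            contig, start, end = row[0], int(row[1]), int(row[2])
            if check(contig, start, end, "panel.bed"):
                panel.append((contig, start, end))

    if errors:
        raise ReferenceError("BED validation failed:\n  " + "\n  ".join(errors))

    ref = MiniReference(
        contigs,
        sorted(segments, key=lambda s: (s.contig, s.start)),
        partner_genes,
        panel,
        rss_config or RssConfig(),
    )
    ref.validate()
    return ref
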