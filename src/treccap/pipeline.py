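"""End-to-end orchestration: map -> detect -> pair -> classify, per sample."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from . import caller as caller_mod
from . import classify as classify_mod
from .caller import JunctionCall, SeedIndex
from .classify import EventCall
from .reference import MiniReference
from .simulate import ReadPair


@dataclass
class CallerParams:
    k: int = caller_mod.DEFAULT_K
    max_mismatch_rate: float = caller_mod.DEFAULT_MAX_MISMATCH_RATE
    min_support: int = caller_mod.DEFAULT_MIN_SUPPORT
    cluster_window: int = caller_mod.DEFAULT_CLUSTER_WINDOW
    pairing_window: int = caller_mod.DEFAULT_PAIRING_WINDOW


@dataclass
class SampleResult:
    sample_id: str
    calls: List[JunctionCall]
    events: List[EventCall]


def call_sample(
    ref: MiniReference,
    pairs: Sequence[ReadPair],
    sample_id: str = "sample",
    params: Optional[CallerParams] = None,
    index: Optional[SeedIndex] = None,
) -> SampleResult:
    """Run the full per-sample pipeline on paired reads."""
    params = params or CallerParams()
    if index is None:
        index = caller_mod.index_reference(ref, params.k)
    alignments = caller_mod.map_pairs(index, pairs, params.max_mismatch_rate)
    calls = caller_mod.detect_junctions(
        alignments, ref, params.min_support, params.cluster_window
    )
    candidates = caller_mod.pair_junctions(calls, ref, params.pairing_window)
    events = classify_mod.classify_sample(candidates, ref, sample_id)
    return SampleResult(sample_id, calls, events)
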