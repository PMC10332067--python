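"""Cohort aggregation and diagnostic concordance metrics.

Per-partner frequency tables follow clinical-report display conventions:
incidence as a percentage with one decimal, per-partner percentages as
integers, both rounded half-up.  A partner gene is *recurrent* when seen
in at least two patients; a patient with two events counts once toward
incidence and twice toward the event total.

Diagnostic metrics (sensitivity, specificity, PPV, NPV) are computed from
a 2x2 confusion table with 95% confidence intervals by the Wilson score
method (default) or the exact (Clopper-Pearson) binomial.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Tuple

import pandas as pd
from statsmodels.stats.proportion import proportion_confint


def round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PartnerRow:
    gene: str
    n_events: int
    pct_of_events: float  # integer-rounded display value
    recurrent: bool


@dataclass
class CohortSummary:
    n_samples: int
    n_positive_samples: int
    n_events: int
    incidence_pct: float
    per_partner: List[PartnerRow]
    events_per_patient: Dict[int, int]
    pct_two_events: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "n_events": r.n_events,
                    "pct_of_events": r.pct_of_events,
                    "recurrent": r.recurrent,
                }
                for r in self.per_partner
            ]
        )

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_positive_samples": self.n_positive_samples,
            "n_events": self.n_events,
            "incidence_pct": self.incidence_pct,
            "per_partner": [
                [r.gene, r.n_events, r.pct_of_events, r.recurrent]
                for r in self.per_partner
            ],
            "events_per_patient": self.events_per_patient,
            "pct_two_events": self.pct_two_events,
        }


def summarize_cohort(events: pd.DataFrame, n_samples: int) -> CohortSummary:
    """Aggregate an event table (columns ``sample_id``, ``partner_gene``).

    ``n_samples`` is the full screened-cohort size, at least the number of
    distinct samples in the table.  Deterministic; permutation-invariant
    to row order.
    """
    if events.empty:
        return CohortSummary(n_samples, 0, 0, 0.0, [], {}, 0.0)
    if events["sample_id"].nunique() > n_samples:
        raise ValueError("event table references more samples than n_samples")
    n_events = len(events)
    positive = events["sample_id"].nunique()
    incidence = round_half_up(100.0 * positive / n_samples, 1)

    per_patient = events.groupby("sample_id").size()
    hist: Dict[int, int] = per_patient.value_counts().sort_index().to_dict()
    n_two = sum(v for k, v in hist.items() if k >= 2)
    pct_two = round_half_up(100.0 * n_two / positive, 0)

    counts = events.groupby("partner_gene").size()
    patients = events.groupby("partner_gene")["sample_id"].nunique()
    rows = [
        PartnerRow(
            gene,
            int(counts[gene]),
            round_half_up(100.0 * counts[gene] / n_events, 0),
            bool(patients[gene] >= 2),
        )
        for gene in counts.index
    ]
    rows.sort(key=lambda r: (-r.n_events, r.gene))
    return CohortSummary(
        n_samples, int(positive), int(n_events), incidence, rows,
        {int(k): int(v) for k, v in hist.items()}, pct_two,
    )


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-table counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValueError("confusion table is empty")


@dataclass(frozen=True)
class Metric:
    value: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]

    @property
    def undefined(self) -> bool:
        return self.value is None


def _metric(count: int, nobs: int, ci_method: str) -> Metric:
    if nobs == 0:
        return Metric(None, None, None)
    p = count / nobs
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method=ci_method)
    # guard floating-point drift at the boundaries
    lo = min(max(float(lo), 0.0), p)
    hi = max(min(float(hi), 1.0), p)
    return Metric(p, lo, hi)


def diagnostic_metrics(
    ct: ConfusionTable, ci_method: str = "wilson"
) -> Dict[str, Metric]:
    """Sensitivity, specificity, PPV and NPV with 95% CIs.

    ``ci_method``: "wilson" (score interval, default) or "exact"
    (Clopper-Pearson).  A metric with a zero denominator is reported as
    undefined, never as 0.
    """
    method = {"wilson": "wilson", "exact": "beta"}.get(ci_method)
    if method is None:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return {
        "sensitivity": _metric(ct.tp, ct.tp + ct.fn, method),
        "specificity": _metric(ct.tn, ct.tn + ct.fp, method),
        "ppv": _metric(ct.tp, ct.tp + ct.fp, method),
        "npv": _metric(ct.tn, ct.tn + ct.fn, method),
    }


def confusion_from_labels(
    calls: pd.DataFrame, truth: pd.DataFrame
) -> ConfusionTable:
    """Build a 2x2 table from per-sample call and truth label tables.

    Both frames need ``sample_id`` and a boolean-like ``positive`` column.
    """
    merged = truth.merge(calls, on="sample_id", how="left", suffixes=("_t", "_c"))
    t = merged["positive_t"].astype(bool)
    c = merged["positive_c"].astype("boolean").fillna(False).astype(bool)
    return ConfusionTable(
        tp=int((t & c).sum()),
        fp=int((~t & c).sum()),
        fn=int((t & ~c).sum()),
        tn=int((~t & ~c).sum()),
    )
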