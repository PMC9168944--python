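"""Group-level summaries: per-domain median, 25-75% IQR and impairment frequency."""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict

from .compass import CompassSnapshot, DomainKey
from .errors import ConsistencyError


class DomainSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    instrument_id: str
    domain_id: str
    n_scored: int
    median: Optional[float]
    q25: Optional[float]
    q75: Optional[float]
    impaired_count: int
    #: impaired_count / n_scored, None when no respondent scored the domain
    frequency: Optional[float]
    #: frequency as percent rounded half away from zero, e.g. 20/24 -> 83
    percent: Optional[int]


class CohortSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    cohort_size: int
    domains: tuple[DomainSummary, ...]

    def domain(self, instrument_id: str, domain_id: str) -> DomainSummary:
        for d in self.domains:
            if (d.instrument_id, d.domain_id) == (instrument_id, domain_id):
                return d
        raise KeyError((instrument_id, domain_id))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_cohort(
    snapshots: Sequence[CompassSnapshot],
    *,
    impairment_threshold: float = 100.0,
    percentile_method: str = "linear",
) -> CohortSummary:
    """Per-domain median, 25-75 percentiles and impairment frequency.

    Statistics are computed over non-missing normalized scores only
    (available-case); the denominator ``n_scored`` is reported alongside.
    Percentiles use linear interpolation between closest ranks by default
    (numpy's ``linear`` method); ``percentile_method`` accepts any method
    numpy supports.
    """
    if not snapshots:
        raise ConsistencyError("cannot summarize an empty snapshot set")
    keys = list(snapshots[0].domain_scores().keys())
    key_set = set(keys)
    for snap in snapshots[1:]:
        if set(snap.domain_scores().keys()) != key_set:
            raise ConsistencyError(
                "snapshots cover different domain sets (mixed mappings?)"
            )

    domains: list[DomainSummary] = []
    for key in keys:
        values = []
        for snap in snapshots:
            s = snap.domain_scores()[key]
            if not s.missing:
                values.append(s.normalized)
        n_scored = len(values)
        impaired = sum(1 for v in values if v < impairment_threshold)
        if n_scored:
            arr = np.asarray(values, dtype=float)
            q25, med, q75 = np.percentile(
                arr, [25, 50, 75], method=percentile_method
            )
            freq = impaired / n_scored
            pct = _round_half_away(100.0 * freq)
        else:
            q25 = med = q75 = freq = pct = None
        domains.append(
            DomainSummary(
                instrument_id=key[0],
                domain_id=key[1],
                n_scored=n_scored,
                median=med,
                q25=q25,
                q75=q75,
                impaired_count=impaired,
                frequency=freq,
                percent=pct,
            )
        )
    return CohortSummary(cohort_size=len(snapshots), domains=tuple(domains))


def extent_frequency_table(summary: CohortSummary) -> list[DomainSummary]:
    """Report rows sorted worst-median first.

    Stable ascending sort by median; ties broken by impairment frequency
    descending, then domain id lexicographic. Domains with no scored
    respondents sort last.
    """
    if not summary.domains:
        raise ConsistencyError("empty cohort summary")

    def sort_key(d: DomainSummary):
        med = d.median if d.median is not None else math.inf
        freq = d.frequency if d.frequency is not None else -1.0
        return (med, -freq, d.domain_id)

    return sorted(summary.domains, key=sort_key)
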