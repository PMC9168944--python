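"""Convenience glue: validate + score record sets, group scores into snapshots."""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

from .compass import AreaMapping, ColorScale, CompassSnapshot, assemble_compass
from .errors import ResponseValidationError
from .instruments import (
    DEFAULT_PRORATION_FLOOR,
    DomainScore,
    InstrumentDefinition,
    ResponseRecord,
    score_instrument,
    validate_responses,
)

ScoredRow = tuple[ResponseRecord, DomainScore]


def score_records(
    records: Sequence[ResponseRecord],
    catalog: Mapping[str, InstrumentDefinition],
    *,
    proration_floor: float = DEFAULT_PRORATION_FLOOR,
    impairment_threshold: float = 100.0,
) -> list[ScoredRow]:
    """Validate every record against its instrument and score all domains."""
    rows: list[ScoredRow] = []
    for rec in records:
        if rec.instrument_id not in catalog:
            raise ResponseValidationError(
                f"respondent {rec.respondent_id!r}: unknown instrument "
                f"{rec.instrument_id!r}"
            )
        definition = catalog[rec.instrument_id]
        validate_responses(rec, definition)
        for score in score_instrument(
            rec,
            definition,
            proration_floor=proration_floor,
            impairment_threshold=impairment_threshold,
        ):
            rows.append((rec, score))
    return rows


def build_snapshots(
    rows: Iterable[ScoredRow],
    mapping: AreaMapping,
    scale: ColorScale = ColorScale(),
    *,
    timepoint: Optional[str] = None,
) -> list[CompassSnapshot]:
    """Group scored domains by respondent+timepoint and assemble compasses.

    ``timepoint`` filters to one follow-up before assembly. Snapshots are
    returned sorted by (respondent_id, timepoint_index) for determinism.
    """
    groups: dict[tuple[str, str, int], list[DomainScore]] = {}
    for rec, score in rows:
        if timepoint is not None and rec.timepoint != timepoint:
            continue
        key = (rec.respondent_id, rec.timepoint, rec.timepoint_index)
        groups.setdefault(key, []).append(score)
    snapshots = []
    for (rid, tp, tp_idx) in sorted(groups, key=lambda k: (k[0], k[2], k[1])):
        snapshots.append(
            assemble_compass(
                groups[(rid, tp, tp_idx)],
                mapping,
                scale,
                respondent_id=rid,
                timepoint=tp,
                timepoint_index=tp_idx,
            )
        )
    return snapshots
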