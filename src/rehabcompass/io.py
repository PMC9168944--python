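"""Reading and writing the tool's tabular and JSON interchange formats.

Response input/output is a long-format CSV with header
``respondent_id,timepoint,instrument_id,item_id,value`` (blank value =
explicit missing), or an equivalent JSON document. Timepoint ordinal
indices are recovered from a leading integer in the label ("3-month" -> 3);
labels without one are ranked by order of first appearance.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .compass import CompassDelta, CompassSnapshot
from .cohort import CohortSummary
from .errors import ResponseValidationError
from .instruments import DomainScore, ResponseRecord

RESPONSE_HEADER = ["respondent_id", "timepoint", "instrument_id", "item_id", "value"]
SCORE_HEADER = [
    "respondent_id",
    "timepoint",
    "instrument_id",
    "domain_id",
    "raw",
    "normalized",
    "n_answered",
    "n_total",
    "impaired",
    "missing",
]


def _timepoint_indices(labels: Sequence[str]) -> dict[str, int]:
    def leading_int(label: str) -> Optional[int]:
        digits = ""
        for ch in label:
            if ch.isdigit():
                digits += ch
            else:
                break
        return int(digits) if digits else None

    seen = list(dict.fromkeys(labels))
    if all(leading_int(lb) is not None for lb in seen):
        return {lb: leading_int(lb) for lb in seen}
    return {lb: i + 1 for i, lb in enumerate(seen)}


def write_responses_csv(
    records: Iterable[ResponseRecord], path: Union[str, Path]
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESPONSE_HEADER)
        for rec in records:
            for item_id, code in rec.answers.items():
                writer.writerow(
                    [
                        rec.respondent_id,
                        rec.timepoint,
                        rec.instrument_id,
                        item_id,
                        "" if code is None else code,
                    ]
                )


def read_responses_csv(path: Union[str, Path]) -> list[ResponseRecord]:
    """Parse long-format response rows back into one record per
    respondent/timepoint/instrument, preserving explicit missingness."""
    groups: dict[tuple[str, str, str], dict[str, Optional[int]]] = {}
    labels: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != RESPONSE_HEADER:
            raise ResponseValidationError(
                f"{path}: expected header {','.join(RESPONSE_HEADER)!r}, "
                f"got {','.join(header or [])!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell for cell in row):
                continue
            if len(row) != 5:
                raise ResponseValidationError(
                    f"{path}:{lineno}: expected 5 fields, got {len(row)}"
                )
            rid, tp, inst, item, value = row
            if value == "":
                code: Optional[int] = None
            else:
                try:
                    code = int(value)
                except ValueError as exc:
                    raise ResponseValidationError(
                        f"{path}:{lineno}: value {value!r} for item {item!r} "
                        "is not an integer response code"
                    ) from exc
            key = (rid, tp, inst)
            answers = groups.setdefault(key, {})
            if item in answers:
                raise ResponseValidationError(
                    f"{path}:{lineno}: duplicate entry for item {item!r} "
                    f"(respondent {rid!r}, timepoint {tp!r})"
                )
            answers[item] = code
            labels.append(tp)
    idx = _timepoint_indices(labels)
    return [
        ResponseRecord(
            respondent_id=rid,
            timepoint=tp,
            timepoint_index=idx[tp],
            instrument_id=inst,
            answers=answers,
        )
        for (rid, tp, inst), answers in groups.items()
    ]


def write_responses_json(
    records: Iterable[ResponseRecord], path: Union[str, Path]
) -> None:
    payload = [rec.model_dump(mode="json") for rec in records]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_responses_json(path: Union[str, Path]) -> list[ResponseRecord]:
    payload = json.loads(Path(path).read_text())
    return [ResponseRecord(**doc) for doc in payload]


# ---------------------------------------------------------------------------
# score export


def write_scores_csv(
    rows: Iterable[tuple[ResponseRecord, DomainScore]], path: Union[str, Path]
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCORE_HEADER)
        for rec, score in rows:
            writer.writerow(
                [
                    rec.respondent_id,
                    rec.timepoint,
                    score.instrument_id,
                    score.domain_id,
                    "" if score.raw is None else repr(score.raw),
                    "" if score.normalized is None else repr(score.normalized),
                    score.n_items_answered,
                    score.n_items_total,
                    score.impaired,
                    score.missing,
                ]
            )


def write_scores_json(
    rows: Iterable[tuple[ResponseRecord, DomainScore]], path: Union[str, Path]
) -> None:
    payload = [
        {
            "respondent_id": rec.respondent_id,
            "timepoint": rec.timepoint,
            **score.model_dump(mode="json"),
        }
        for rec, score in rows
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# snapshot / delta / summary export


def snapshot_to_json(snapshot: CompassSnapshot, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(snapshot.model_dump(mode="json"), indent=2) + "\n")


def delta_to_json(delta: CompassDelta, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(delta.model_dump(mode="json"), indent=2) + "\n")


def write_summary_csv(summary: CohortSummary, path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "instrument_id",
                "domain_id",
                "n_scored",
                "median",
                "q25",
                "q75",
                "impaired_count",
                "frequency",
                "percent",
            ]
        )
        for d in summary.domains:
            writer.writerow(
                [
                    d.instrument_id,
                    d.domain_id,
                    d.n_scored,
                    "" if d.median is None else d.median,
                    "" if d.q25 is None else d.q25,
                    "" if d.q75 is None else d.q75,
                    d.impaired_count,
                    "" if d.frequency is None else d.frequency,
                    "" if d.percent is None else d.percent,
                ]
            )


def write_summary_json(summary: CohortSummary, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(summary.model_dump(mode="json"), indent=2) + "\n")
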