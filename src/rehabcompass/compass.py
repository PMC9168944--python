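"""Seven-area compass assembly, color banding, impairment flags and deltas."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConsistencyError, DefinitionError, ScoringError
from .instruments import DomainScore, InstrumentDefinition

#: The fixed identifiers of the seven functional areas, in default order.
AREA_IDS = (
    "life",
    "cognition",
    "emotion",
    "fatigue",
    "sexuality_continence",
    "sensory",
    "motor",
)

DomainKey = tuple[str, str]  # (instrument_id, domain_id)


class ColorScale(BaseModel):
    """Triage bands on the 0-100 scale: red worst, green best, orange between.

    Bounds are closed on the red and green side: red = [0, red_max],
    orange = (red_max, green_min), green = [green_min, 100].
    """

    model_config = ConfigDict(frozen=True)

    red_max: float = 30.0
    green_min: float = 70.0

    @model_validator(mode="after")
    def _check(self):
        if not 0 <= self.red_max < self.green_min <= 100:
            raise ValueError(
                f"need 0 <= red_max < green_min <= 100, "
                f"got {self.red_max}, {self.green_min}"
            )
        return self


def band(score: float, scale: ColorScale = ColorScale()) -> str:
    """Band label ('red' | 'orange' | 'green') for a 0-100 score."""
    if not 0 <= score <= 100:
        raise ScoringError(f"score {score} outside [0, 100]")
    if score <= scale.red_max:
        return "red"
    if score >= scale.green_min:
        return "green"
    return "orange"


def flag_impairment(score: DomainScore, threshold: float = 100.0) -> bool:
    """True iff the scored domain falls below the impairment threshold.

    The default rule flags any normalized value below 100. Missing scores
    are an error: the caller must handle missingness explicitly.
    """
    if score.missing or score.normalized is None:
        raise ScoringError(
            f"domain {score.domain_id!r} is missing; impairment undefined"
        )
    return score.normalized < threshold


# ---------------------------------------------------------------------------
# area mapping


class AreaDefinition(BaseModel):
    model_config = ConfigDict(frozen=True)

    area_id: str
    name: str = ""
    members: tuple[DomainKey, ...]

    @model_validator(mode="before")
    @classmethod
    def _coerce_members(cls, data):
        if isinstance(data, Mapping) and "members" in data:
            data = {**data, "members": [tuple(m) for m in data["members"]]}
        return data


class AreaMapping(BaseModel):
    """Ordered assignment of scored domains to the seven compass areas."""

    model_config = ConfigDict(frozen=True)

    areas: tuple[AreaDefinition, ...]

    @model_validator(mode="after")
    def _check(self):
        ids = [a.area_id for a in self.areas]
        if len(ids) != 7 or set(ids) != set(AREA_IDS):
            raise ValueError(
                f"mapping must define exactly the seven areas {sorted(AREA_IDS)}, "
                f"got {ids}"
            )
        seen: set[DomainKey] = set()
        for area in self.areas:
            for key in area.members:
                if key in seen:
                    raise ValueError(
                        f"domain {key} mapped to more than one area"
                    )
                seen.add(key)
        return self

    @property
    def member_keys(self) -> tuple[DomainKey, ...]:
        return tuple(k for a in self.areas for k in a.members)

    def validate_against_catalog(
        self, catalog: Mapping[str, InstrumentDefinition]
    ) -> "AreaMapping":
        for area in self.areas:
            for inst_id, dom_id in area.members:
                if inst_id not in catalog:
                    raise DefinitionError(
                        f"area {area.area_id!r}: unknown instrument {inst_id!r}"
                    )
                catalog[inst_id].domain(dom_id)  # raises if absent
        return self


def load_area_mapping(source: Union[str, Path, Mapping, None] = None) -> AreaMapping:
    """Load an area mapping YAML; ``None`` loads the packaged default."""
    if source is None:
        source = Path(str(resources.files("rehabcompass"))) / "data/area_mapping.yaml"
    if isinstance(source, Mapping):
        doc = source
    else:
        doc = yaml.safe_load(Path(source).read_text())
    try:
        return AreaMapping(**doc)
    except Exception as exc:
        raise DefinitionError(f"invalid area mapping: {exc}") from exc


# ---------------------------------------------------------------------------
# snapshot assembly


class CompassArea(BaseModel):
    model_config = ConfigDict(frozen=True)

    area_id: str
    name: str = ""
    members: tuple[DomainScore, ...]
    area_score: Optional[float]  # mean of non-missing member scores
    min_score: Optional[float]
    area_band: Optional[str]
    min_band: Optional[str]
    missing: bool


class CompassSnapshot(BaseModel):
    model_config = ConfigDict(frozen=True)

    respondent_id: str
    timepoint: str
    timepoint_index: int
    areas: tuple[CompassArea, ...]

    def area(self, area_id: str) -> CompassArea:
        for a in self.areas:
            if a.area_id == area_id:
                return a
        raise KeyError(area_id)

    def domain_scores(self) -> dict[DomainKey, DomainScore]:
        return {
            (s.instrument_id, s.domain_id): s for a in self.areas for s in a.members
        }


def assemble_compass(
    domain_scores: Iterable[DomainScore],
    mapping: AreaMapping,
    scale: ColorScale = ColorScale(),
    *,
    respondent_id: str,
    timepoint: str = "",
    timepoint_index: int = 0,
) -> CompassSnapshot:
    """Assemble one respondent-timepoint snapshot from scored domains.

    area_score is the available-case arithmetic mean of member normalized
    scores; min_score their minimum. An area whose members are all missing
    is flagged missing (it renders neutral). A mapped domain absent from
    ``domain_scores`` is a consistency error — missingness must be explicit.
    """
    by_key: dict[DomainKey, DomainScore] = {}
    for s in domain_scores:
        by_key[(s.instrument_id, s.domain_id)] = s
    areas: list[CompassArea] = []
    for area in mapping.areas:
        members: list[DomainScore] = []
        for key in area.members:
            if key not in by_key:
                raise ConsistencyError(
                    f"respondent {respondent_id!r}: domain {key} is mapped to "
                    f"area {area.area_id!r} but absent from the scored input"
                )
            members.append(by_key[key])
        scored = [m.normalized for m in members if not m.missing]
        if scored:
            area_score = sum(scored) / len(scored)
            min_score = min(scored)
            areas.append(
                CompassArea(
                    area_id=area.area_id,
                    name=area.name,
                    members=tuple(members),
                    area_score=area_score,
                    min_score=min_score,
                    area_band=band(area_score, scale),
                    min_band=band(min_score, scale),
                    missing=False,
                )
            )
        else:
            areas.append(
                CompassArea(
                    area_id=area.area_id,
                    name=area.name,
                    members=tuple(members),
                    area_score=None,
                    min_score=None,
                    area_band=None,
                    min_band=None,
                    missing=True,
                )
            )
    return CompassSnapshot(
        respondent_id=respondent_id,
        timepoint=timepoint,
        timepoint_index=timepoint_index,
        areas=tuple(areas),
    )


# ---------------------------------------------------------------------------
# longitudinal deltas


class DomainDelta(BaseModel):
    model_config = ConfigDict(frozen=True)

    instrument_id: str
    domain_id: str
    change: Optional[float]  # later - earlier, None when not comparable
    band_from: Optional[str]
    band_to: Optional[str]
    newly_missing: bool
    newly_scored: bool


class AreaDelta(BaseModel):
    model_config = ConfigDict(frozen=True)

    area_id: str
    change: Optional[float]
    band_from: Optional[str]
    band_to: Optional[str]
    newly_missing: bool
    newly_scored: bool


class CompassDelta(BaseModel):
    model_config = ConfigDict(frozen=True)

    respondent_id: str
    timepoint_from: str
    timepoint_to: str
    domains: tuple[DomainDelta, ...]
    areas: tuple[AreaDelta, ...]


def compare_snapshots(
    earlier: CompassSnapshot, later: CompassSnapshot
) -> CompassDelta:
    """Signed score changes (later - earlier) and band transitions.

    Domains or areas missing at either end are flagged, never differenced.
    """
    if earlier.respondent_id != later.respondent_id:
        raise ConsistencyError(
            f"respondent mismatch: {earlier.respondent_id!r} vs "
            f"{later.respondent_id!r}"
        )
    e_scores = earlier.domain_scores()
    l_scores = later.domain_scores()
    if set(e_scores) != set(l_scores) or [a.area_id for a in earlier.areas] != [
        a.area_id for a in later.areas
    ]:
        raise ConsistencyError("snapshots were assembled under different mappings")

    domains: list[DomainDelta] = []
    for key in e_scores:
        e, l = e_scores[key], l_scores[key]
        comparable = not e.missing and not l.missing
        scale = ColorScale()
        domains.append(
            DomainDelta(
                instrument_id=key[0],
                domain_id=key[1],
                change=(l.normalized - e.normalized) if comparable else None,
                band_from=band(e.normalized, scale) if not e.missing else None,
                band_to=band(l.normalized, scale) if not l.missing else None,
                newly_missing=not e.missing and l.missing,
                newly_scored=e.missing and not l.missing,
            )
        )
    areas: list[AreaDelta] = []
    for e_area, l_area in zip(earlier.areas, later.areas):
        comparable = not e_area.missing and not l_area.missing
        areas.append(
            AreaDelta(
                area_id=e_area.area_id,
                change=(l_area.area_score - e_area.area_score) if comparable else None,
                band_from=e_area.area_band,
                band_to=l_area.area_band,
                newly_missing=not e_area.missing and l_area.missing,
                newly_scored=e_area.missing and not l_area.missing,
            )
        )
    return CompassDelta(
        respondent_id=earlier.respondent_id,
        timepoint_from=earlier.timepoint,
        timepoint_to=later.timepoint,
        domains=tuple(domains),
        areas=tuple(areas),
    )
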