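"""Instrument engine: item banks, response validation, scoring, normalization.

Instruments are declared as YAML documents (one per instrument) and loaded
into :class:`InstrumentDefinition` objects. Every domain score is normalized
onto a common 0-100 scale where 100 is the best achievable health state,
regardless of the instrument's native direction.

Scoring rules
-------------
``mean-rescale``
    raw = mean of answered member items; linear rescale of the item mean.
``sum-rescale`` / ``per-dimension-rescale``
    raw = prorated sum (mean of answered items x total item count).
``grade-rescale``
    yes/no items resolve to a global grade through a severity-ordered
    cascade; ambiguous answer sets resolve to missing rather than a guess.
``passthrough-0-100``
    the single item's value already lives on the 0-100 best-health scale.
"""

from __future__ import annotations

import datetime as _dt
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import DefinitionError, ResponseValidationError, ScoringError

ScoringRule = Literal[
    "mean-rescale",
    "sum-rescale",
    "grade-rescale",
    "per-dimension-rescale",
    "passthrough-0-100",
]

#: Instrument ids shipped as packaged defaults.
DEFAULT_INSTRUMENT_IDS = ("sis3", "sis_plus", "hads", "fas", "smrsq", "eq5d3l", "eat10")

#: Fraction of a domain's items that must be answered for proration.
DEFAULT_PRORATION_FLOOR = 0.5

_EPS = 1e-9


class ResponseLevel(BaseModel):
    model_config = ConfigDict(frozen=True)

    code: int
    label: str = ""


class ItemDefinition(BaseModel):
    """One questionnaire item with its admissible integer response codes."""

    model_config = ConfigDict(frozen=True)

    item_id: str
    prompt: str = ""
    levels: tuple[ResponseLevel, ...]
    domain_id: str = ""
    grade: Optional[int] = None  # grade-rescale cascade target, else None

    @field_validator("levels", mode="before")
    @classmethod
    def _coerce_levels(cls, v):
        if isinstance(v, Mapping) and set(v) == {"min", "max"}:
            return tuple(
                ResponseLevel(code=c, label=str(c))
                for c in range(int(v["min"]), int(v["max"]) + 1)
            )
        out = []
        for lv in v:
            if isinstance(lv, int):
                out.append(ResponseLevel(code=lv, label=str(lv)))
            elif isinstance(lv, ResponseLevel):
                out.append(lv)
            else:
                out.append(ResponseLevel(**lv))
        return tuple(out)

    @model_validator(mode="after")
    def _check_levels(self):
        codes = [lv.code for lv in self.levels]
        if len(codes) < 2:
            raise ValueError(f"item {self.item_id!r}: needs >=2 levels")
        if any(b <= a for a, b in zip(codes, codes[1:])):
            raise ValueError(
                f"item {self.item_id!r}: level codes must be strictly increasing"
            )
        return self

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(lv.code for lv in self.levels)


class DomainDefinition(BaseModel):
    model_config = ConfigDict(frozen=True)

    domain_id: str
    name: str = ""
    raw_min: float
    raw_max: float
    items: tuple[ItemDefinition, ...]
    scoring_rule: Optional[ScoringRule] = None  # falls back to instrument rule
    higher_is_better: Optional[bool] = None  # falls back to instrument flag

    @model_validator(mode="after")
    def _check(self):
        if not self.items:
            raise ValueError(f"domain {self.domain_id!r}: needs >=1 item")
        if not self.raw_min < self.raw_max:
            raise ValueError(
                f"domain {self.domain_id!r}: raw_min must be < raw_max "
                f"(got {self.raw_min}, {self.raw_max})"
            )
        return self


class InstrumentDefinition(BaseModel):
    """Declarative item bank and scoring rule for one PROM instrument."""

    model_config = ConfigDict(frozen=True)

    instrument_id: str
    name: str = ""
    scoring_rule: ScoringRule
    higher_is_better: bool
    domains: tuple[DomainDefinition, ...]

    @model_validator(mode="before")
    @classmethod
    def _stamp_domain_ids(cls, data):
        if isinstance(data, dict) and "domains" in data:
            domains = []
            for dom in data["domains"]:
                dom = dict(dom) if isinstance(dom, Mapping) else dom
                if isinstance(dom, dict):
                    dom["items"] = [
                        {**(it if isinstance(it, Mapping) else it.model_dump()),
                         "domain_id": dom.get("domain_id", "")}
                        for it in dom.get("items", ())
                    ]
                domains.append(dom)
            data = {**data, "domains": domains}
        return data

    @model_validator(mode="after")
    def _check(self):
        if not self.domains:
            raise ValueError(
                f"instrument {self.instrument_id!r}: needs >=1 domain"
            )
        seen: set[str] = set()
        for dom in self.domains:
            for it in dom.items:
                if it.item_id in seen:
                    raise ValueError(
                        f"instrument {self.instrument_id!r}: item {it.item_id!r} "
                        "appears in more than one domain or is duplicated"
                    )
                seen.add(it.item_id)
        dids = [d.domain_id for d in self.domains]
        if len(dids) != len(set(dids)):
            raise ValueError(
                f"instrument {self.instrument_id!r}: duplicate domain ids"
            )
        return self

    # -- lookup helpers -------------------------------------------------
    @property
    def items(self) -> tuple[ItemDefinition, ...]:
        return tuple(it for dom in self.domains for it in dom.items)

    def item(self, item_id: str) -> ItemDefinition:
        for dom in self.domains:
            for it in dom.items:
                if it.item_id == item_id:
                    return it
        raise KeyError(item_id)

    def domain(self, domain_id: str) -> DomainDefinition:
        for dom in self.domains:
            if dom.domain_id == domain_id:
                return dom
        raise ScoringError(
            f"instrument {self.instrument_id!r} has no domain {domain_id!r}"
        )

    def rule_for(self, domain: DomainDefinition) -> ScoringRule:
        return domain.scoring_rule or self.scoring_rule

    def orientation_for(self, domain: DomainDefinition) -> bool:
        if domain.higher_is_better is not None:
            return domain.higher_is_better
        return self.higher_is_better

    def best_code_for(self, item: ItemDefinition) -> int:
        dom = self.domain(item.domain_id)
        return item.codes[-1] if self.orientation_for(dom) else item.codes[0]

    def worst_code_for(self, item: ItemDefinition) -> int:
        dom = self.domain(item.domain_id)
        return item.codes[0] if self.orientation_for(dom) else item.codes[-1]


class ResponseRecord(BaseModel):
    """One respondent's item-level answers for one instrument at one time point.

    ``answers`` maps item id to an integer response code; ``None`` is the
    explicit-missing marker (never 0, which is a valid code on some scales).
    """

    respondent_id: str
    timepoint: str
    timepoint_index: int
    instrument_id: str
    answers: dict[str, Optional[int]] = Field(default_factory=dict)
    completed_on: Optional[_dt.date] = None


class DomainScore(BaseModel):
    """A scored, normalized (0-100, 100 = best) functional domain."""

    instrument_id: str
    domain_id: str
    raw: Optional[float]
    normalized: Optional[float]
    n_items_total: int
    n_items_answered: int
    impaired: bool
    missing: bool

    @model_validator(mode="after")
    def _check(self):
        if not self.missing:
            if self.normalized is None or not -_EPS <= self.normalized <= 100 + _EPS:
                raise ValueError("normalized must be in [0, 100] when scored")
        if self.n_items_answered > self.n_items_total:
            raise ValueError("n_items_answered > n_items_total")
        return self


# ---------------------------------------------------------------------------
# catalog loading


def _load_one(source: Union[str, Path, Mapping]) -> InstrumentDefinition:
    if isinstance(source, Mapping):
        doc, where = source, "<dict>"
    else:
        path = Path(source)
        where = str(path)
        try:
            doc = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise DefinitionError(f"{where}: malformed YAML: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise DefinitionError(f"{where}: expected a mapping at document root")
    try:
        return InstrumentDefinition(**doc)
    except Exception as exc:  # pydantic ValidationError or ValueError
        raise DefinitionError(f"{where}: {exc}") from exc


def load_instrument_catalog(
    sources: Iterable[Union[str, Path, Mapping]],
) -> dict[str, InstrumentDefinition]:
    """Load instrument definitions into a catalog keyed by instrument id.

    Raises
    ------
    DefinitionError
        On schema violations (naming the file and offending field) and on
        duplicate instrument ids across files.
    """
    catalog: dict[str, InstrumentDefinition] = {}
    for src in sources:
        inst = _load_one(src)
        if inst.instrument_id in catalog:
            raise DefinitionError(
                f"duplicate instrument id {inst.instrument_id!r}"
            )
        catalog[inst.instrument_id] = inst
    return catalog


def default_instrument_paths() -> list[Path]:
    root = resources.files("rehabcompass").joinpath("data/instruments")
    return sorted(Path(str(root)).glob("*.yaml"))


def default_catalog() -> dict[str, InstrumentDefinition]:
    """The packaged six-instrument default catalog."""
    return load_instrument_catalog(default_instrument_paths())


# ---------------------------------------------------------------------------
# validation


def validate_responses(
    record: ResponseRecord, definition: InstrumentDefinition
) -> ResponseRecord:
    """Check every answer against the instrument's item bank.

    Returns the record unchanged when valid; unanswered items stay
    explicit-missing. Raises :class:`ResponseValidationError` naming the
    offending item and code otherwise.
    """
    if record.instrument_id != definition.instrument_id:
        raise ResponseValidationError(
            f"record is for instrument {record.instrument_id!r}, "
            f"definition is {definition.instrument_id!r}"
        )
    known = {it.item_id: it for it in definition.items}
    for item_id, code in record.answers.items():
        if item_id not in known:
            raise ResponseValidationError(
                f"respondent {record.respondent_id!r}: unknown item {item_id!r} "
                f"for instrument {definition.instrument_id!r}"
            )
        if code is None:
            continue
        admissible = known[item_id].codes
        if code not in admissible:
            raise ResponseValidationError(
                f"respondent {record.respondent_id!r}: item {item_id!r} "
                f"code {code!r} not in admissible levels {list(admissible)}"
            )
    return record


# ---------------------------------------------------------------------------
# scoring


def normalize_score(
    raw: float, bounds: tuple[float, float], higher_is_better: bool
) -> float:
    """Linearly map a raw score onto 0-100 where 100 = best health.

    Clamping is applied only against floating-point round-off; a raw value
    outside ``bounds`` raises :class:`ScoringError`.
    """
    lo, hi = bounds
    if not lo - _EPS <= raw <= hi + _EPS:
        raise ScoringError(f"raw value {raw} outside bounds [{lo}, {hi}]")
    frac = (raw - lo) / (hi - lo)
    if not higher_is_better:
        frac = 1.0 - frac
    return min(100.0, max(0.0, 100.0 * frac))


def _resolve_grade(
    domain: DomainDefinition, answers: Mapping[str, Optional[int]]
) -> Optional[float]:
    """Severity-ordered yes/no cascade: first 'yes' fixes the grade.

    A missing answer encountered before any 'yes' makes the grade
    unresolvable (returns None) — fail-safe over guessing.
    """
    ordered = sorted(domain.items, key=lambda it: -(it.grade or 0))
    for it in ordered:
        code = answers.get(it.item_id)
        if code is None:
            return None
        if code == it.codes[-1]:  # 'yes'
            return float(it.grade if it.grade is not None else 0)
    return 0.0


def score_domain(
    record: ResponseRecord,
    definition: InstrumentDefinition,
    domain_id: str,
    *,
    proration_floor: float = DEFAULT_PRORATION_FLOOR,
    impairment_threshold: float = 100.0,
) -> DomainScore:
    """Score one domain of a validated record.

    A domain is scored by prorated aggregation when the answered fraction is
    at least ``proration_floor``; otherwise ``missing`` is True and no
    normalized value is produced. ``impaired`` is True iff the domain is
    scored and its normalized value is strictly below ``impairment_threshold``.
    """
    domain = definition.domain(domain_id)
    rule = definition.rule_for(domain)
    orientation = definition.orientation_for(domain)
    answered = [
        (it, record.answers.get(it.item_id))
        for it in domain.items
        if record.answers.get(it.item_id) is not None
    ]
    n_total = len(domain.items)
    n_answered = len(answered)

    raw: Optional[float]
    if rule == "grade-rescale":
        raw = _resolve_grade(domain, record.answers)
    elif rule == "passthrough-0-100":
        raw = float(answered[0][1]) if answered else None
    else:  # mean-rescale, sum-rescale, per-dimension-rescale
        if n_total and n_answered / n_total >= proration_floor and n_answered > 0:
            mean = sum(code for _, code in answered) / n_answered
            raw = mean if rule == "mean-rescale" else mean * n_total
        else:
            raw = None

    if raw is None:
        return DomainScore(
            instrument_id=definition.instrument_id,
            domain_id=domain_id,
            raw=None,
            normalized=None,
            n_items_total=n_total,
            n_items_answered=n_answered,
            impaired=False,
            missing=True,
        )

    normalized = normalize_score(raw, (domain.raw_min, domain.raw_max), orientation)
    return DomainScore(
        instrument_id=definition.instrument_id,
        domain_id=domain_id,
        raw=raw,
        normalized=normalized,
        n_items_total=n_total,
        n_items_answered=n_answered,
        impaired=normalized < impairment_threshold,
        missing=False,
    )


def score_instrument(
    record: ResponseRecord,
    definition: InstrumentDefinition,
    *,
    proration_floor: float = DEFAULT_PRORATION_FLOOR,
    impairment_threshold: float = 100.0,
) -> list[DomainScore]:
    """Score every domain of the instrument, in definition order."""
    return [
        score_domain(
            record,
            definition,
            dom.domain_id,
            proration_floor=proration_floor,
            impairment_threshold=impairment_threshold,
        )
        for dom in definition.domains
    ]
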