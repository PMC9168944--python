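"""Seeded synthetic cohort generator.

Emits item-level :class:`ResponseRecord` objects for a configurable cohort
with controllable per-domain impairment prevalence and severity, so every
pipeline stage is testable without patient data.

Severity model: an impaired respondent answers each item of the impaired
domain at the best level with probability ``item_best_prob``, otherwise at a
level shifted toward the worse pole by ``1 + Binomial(n_worse - 1,
severity)`` steps. At least one item is forced off the best level so the
domain is guaranteed to score below 100. The model is a documented
convention, not a reconstruction of any published generative process.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .compass import AreaMapping
from .errors import ConfigError
from .instruments import (
    DomainDefinition,
    InstrumentDefinition,
    ResponseRecord,
)


class TimepointSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    label: str
    index: int  # ordinal, 1-based


class CohortProfile(BaseModel):
    """Generator configuration; the seed fixes the output byte-for-byte."""

    model_config = ConfigDict(frozen=True)

    size: int = 24
    seed: int = 0
    mode: Literal["exact-count", "probabilistic"] = "exact-count"
    timepoints: tuple[TimepointSpec, ...] = (
        TimepointSpec(label="12-month", index=1),
    )
    #: multiplicative reduction of prevalence per later timepoint
    improvement_drift: float = 0.0
    #: worseness of shifted answers, in [0, 1]
    severity: float = 0.5
    #: probability an impaired respondent still answers an item at best level
    item_best_prob: float = 0.3
    #: target impairment prevalence per domain, keyed "instrument_id:domain_id"
    prevalence: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self):
        if self.size < 1:
            raise ValueError("size must be >= 1")
        for knob in ("severity", "item_best_prob", "improvement_drift"):
            v = getattr(self, knob)
            if not 0 <= v <= 1:
                raise ValueError(f"{knob} must be in [0, 1], got {v}")
        for key, p in self.prevalence.items():
            if ":" not in key:
                raise ValueError(
                    f"prevalence key {key!r} must be 'instrument_id:domain_id'"
                )
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {key!r} must be in [0, 1]")
        return self

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "CohortProfile":
        doc = yaml.safe_load(Path(path).read_text())
        try:
            return cls(**(doc or {}))
        except Exception as exc:
            raise ConfigError(f"{path}: invalid cohort profile: {exc}") from exc


def _respondent_ids(size: int) -> list[str]:
    width = max(2, len(str(size)))
    return [f"r{i:0{width}d}" for i in range(1, size + 1)]


def _draw_impaired_items(
    rng: np.random.Generator,
    definition: InstrumentDefinition,
    domain: DomainDefinition,
    severity: float,
    item_best_prob: float,
) -> dict[str, int]:
    """Item answers guaranteed to score the domain strictly below 100."""
    rule = definition.rule_for(domain)
    if rule == "grade-rescale":
        grades = sorted(it.grade or 0 for it in domain.items)
        g = grades[min(len(grades) - 1, int(rng.binomial(len(grades) - 1, severity)))]
        g = max(g, min(gr for gr in grades if gr > 0))  # at least grade 1
        answers = {}
        for it in domain.items:
            yes = (it.grade or 0) <= g and (it.grade or 0) > 0
            answers[it.item_id] = it.codes[-1] if yes else it.codes[0]
        return answers

    answers = {}
    off_best: list[str] = []
    for it in domain.items:
        codes = list(it.codes)
        if definition.orientation_for(domain):
            codes.reverse()  # codes[0] is now best, last is worst
        n_worse = len(codes) - 1
        if rng.random() < item_best_prob:
            answers[it.item_id] = codes[0]
        else:
            shift = 1 + int(rng.binomial(n_worse - 1, severity)) if n_worse > 1 else 1
            answers[it.item_id] = codes[shift]
            off_best.append(it.item_id)
    if not off_best:  # force impairment: one item one step toward worse
        it = domain.items[int(rng.integers(len(domain.items)))]
        codes = list(it.codes)
        if definition.orientation_for(domain):
            codes.reverse()
        answers[it.item_id] = codes[1]
    return answers


def _best_items(
    definition: InstrumentDefinition, domain: DomainDefinition
) -> dict[str, int]:
    return {it.item_id: definition.best_code_for(it) for it in domain.items}


def generate_cohort(
    profile: CohortProfile,
    catalog: Mapping[str, InstrumentDefinition],
    mapping: AreaMapping,
) -> list[ResponseRecord]:
    """Generate item-level records for every respondent/instrument/timepoint.

    Respondents not targeted as impaired in a domain answer all its items at
    the best level. In exact-count mode exactly ``round(prevalence * size)``
    respondents are impaired per domain (deterministic allocation); in
    probabilistic mode each respondent is impaired independently with the
    target probability.
    """
    for key in profile.prevalence:
        inst_id, _, dom_id = key.partition(":")
        if inst_id not in catalog:
            raise ConfigError(f"prevalence for unknown instrument {inst_id!r}")
        catalog[inst_id].domain(dom_id)  # raises ScoringError if absent

    rng = np.random.default_rng(profile.seed)
    respondents = _respondent_ids(profile.size)
    instrument_ids = sorted({inst for inst, _ in mapping.member_keys})

    # Deterministic per-domain impairment order, shared across timepoints so
    # improvement drift shrinks the same impaired pool monotonically.
    domain_order: dict[str, np.ndarray] = {}
    all_domain_keys = sorted(
        f"{inst_id}:{dom.domain_id}"
        for inst_id in instrument_ids
        for dom in catalog[inst_id].domains
    )
    for key in all_domain_keys:
        domain_order[key] = rng.permutation(profile.size)

    records: list[ResponseRecord] = []
    for tp in sorted(profile.timepoints, key=lambda t: t.index):
        decay = (1.0 - profile.improvement_drift) ** (tp.index - 1)
        impaired_sets: dict[str, set[int]] = {}
        for key in all_domain_keys:
            prev = profile.prevalence.get(key, 0.0) * decay
            if profile.mode == "exact-count":
                count = int(np.floor(prev * profile.size + 0.5))
                impaired_sets[key] = set(domain_order[key][:count].tolist())
            else:
                draws = rng.random(profile.size) < prev
                impaired_sets[key] = set(np.flatnonzero(draws).tolist())
        for idx, rid in enumerate(respondents):
            for inst_id in instrument_ids:
                definition = catalog[inst_id]
                answers: dict[str, Optional[int]] = {}
                for dom in definition.domains:
                    key = f"{inst_id}:{dom.domain_id}"
                    if idx in impaired_sets[key]:
                        answers.update(
                            _draw_impaired_items(
                                rng,
                                definition,
                                dom,
                                profile.severity,
                                profile.item_best_prob,
                            )
                        )
                    else:
                        answers.update(_best_items(definition, dom))
                records.append(
                    ResponseRecord(
                        respondent_id=rid,
                        timepoint=tp.label,
                        timepoint_index=tp.index,
                        instrument_id=inst_id,
                        answers=answers,
                    )
                )
    return records


def inject_missingness(
    records: Sequence[ResponseRecord], rate: float, seed: int
) -> list[ResponseRecord]:
    """Replace each answer with the explicit-missing marker w.p. ``rate``."""
    if not 0 <= rate <= 1:
        raise ConfigError(f"missingness rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    out: list[ResponseRecord] = []
    for rec in records:
        answers = {
            item_id: (None if rng.random() < rate else code)
            for item_id, code in rec.answers.items()
        }
        out.append(rec.model_copy(update={"answers": answers}))
    return out
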