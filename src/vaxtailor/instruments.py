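"""Survey instruments and scoring.

Defines the two pre-intervention instruments — the 20-item, 6-domain parental
vaccine-values scale on a 4-point agreement scale, and the 13-topic
beliefs/concerns scale on a 5-point agreement scale (three topics are
two-item composites) — plus the 2-item intention measure, and turns raw item
responses into a scored :class:`ParticipantProfile`.

Coding convention: strongly_disagree=1 ... strongly_agree=n_levels, with
explicit per-item polarity reversal for anti-vaccine-worded items, so that a
lower belief score always means a more anti-vaccine view.
"""

from __future__ import annotations

import enum
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .constants import BELIEFS_ID, CONCERN_TOPICS, PVVS_ID, VALUE_DOMAINS

__all__ = [
    "SurveyValidationError",
    "LikertCoding",
    "InstrumentItem",
    "InstrumentDefinition",
    "ScoringPolicy",
    "ResponseRecord",
    "DomainScores",
    "ConcernScores",
    "Intention",
    "IntentionCategory",
    "Demographics",
    "ParticipantProfile",
    "load_instrument",
    "load_default_instruments",
    "score_pvvs",
    "score_concerns",
    "classify_intention",
    "build_profile",
]


class SurveyValidationError(ValueError):
    """Raised when survey input violates an instrument's contract."""


class LikertCoding(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_levels: int
    labels: tuple[str, ...]
    orientation: Literal["higher_is_endorsement"] = "higher_is_endorsement"

    @model_validator(mode="after")
    def _check(self) -> "LikertCoding":
        if self.n_levels not in (4, 5):
            raise ValueError("n_levels must be 4 or 5")
        if len(self.labels) != self.n_levels:
            raise ValueError("label count must equal n_levels")
        return self

    @property
    def numeric_codes(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_levels + 1))


class InstrumentItem(BaseModel):
    model_config = ConfigDict(frozen=True)

    item_id: str
    group: str
    text: str = ""
    polarity: Literal["pro_vaccine", "anti_vaccine", "value_endorsement"]
    reverse_keyed: bool = False


class InstrumentDefinition(BaseModel):
    """Declarative description of one survey scale."""

    model_config = ConfigDict(frozen=True)

    instrument_id: str
    items: tuple[InstrumentItem, ...]
    group_kind: Literal["value_domain", "concern_topic"]
    coding: LikertCoding
    concern_labels: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_structure(self) -> "InstrumentDefinition":
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids")
        groups = self.group_ids
        if self.instrument_id == PVVS_ID:
            if len(self.items) != 20:
                raise ValueError("values instrument must have exactly 20 items")
            if set(groups) != set(VALUE_DOMAINS):
                raise ValueError("values instrument must cover exactly the 6 value domains")
        if self.instrument_id == BELIEFS_ID:
            if set(groups) != set(CONCERN_TOPICS):
                raise ValueError("beliefs instrument must cover exactly the 13 concern topics")
        return self

    @property
    def group_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for it in self.items:
            seen.setdefault(it.group, None)
        return tuple(seen)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def items_in_group(self, group: str) -> tuple[InstrumentItem, ...]:
        return tuple(it for it in self.items if it.group == group)

    def oriented_code(self, item: InstrumentItem, code: int) -> float:
        """Apply polarity reversal: reverse-keyed items map c -> n+1-c."""
        if item.reverse_keyed or item.polarity == "anti_vaccine":
            return float(self.coding.n_levels + 1 - code)
        return float(code)


class ScoringPolicy(BaseModel):
    """Missing-data policy for group scoring.

    The conservative default rejects any record with missing items; with
    ``allow_partial`` a group mean is taken over answered items provided at
    least ``min_fraction`` of the group's items were answered.
    """

    model_config = ConfigDict(frozen=True)

    allow_partial: bool = False
    min_fraction: float = 0.5


class ResponseRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    participant_id: str
    instrument_id: str
    answers: dict[str, int]
    session_index: int = 0
    timestamp: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "ResponseRecord":
        if not (0 <= self.session_index <= 3):
            raise ValueError("session_index must be in 0..3")
        return self


class DomainScores(BaseModel):
    model_config = ConfigDict(frozen=True)

    scores: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "DomainScores":
        if set(self.scores) != set(VALUE_DOMAINS):
            raise ValueError("all six value domains must be present")
        for k, v in self.scores.items():
            if not (1.0 <= v <= 4.0):
                raise ValueError(f"domain score {k}={v} outside [1, 4]")
        return self

    def __getitem__(self, domain: str) -> float:
        return self.scores[domain]


class ConcernScores(BaseModel):
    model_config = ConfigDict(frozen=True)

    scores: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "ConcernScores":
        if set(self.scores) != set(CONCERN_TOPICS):
            raise ValueError("all 13 concern topics must be present")
        for k, v in self.scores.items():
            if not (1.0 <= v <= 5.0):
                raise ValueError(f"concern score {k}={v} outside [1, 5]")
        return self

    def __getitem__(self, concern: str) -> float:
        return self.scores[concern]


class Intention(str, enum.Enum):
    refuses_all = "refuses_all"
    alternative_schedule = "alternative_schedule"
    full_acceptor = "full_acceptor"


class IntentionCategory(BaseModel):
    model_config = ConfigDict(frozen=True)

    value: Intention
    hesitant: bool

    @model_validator(mode="after")
    def _check(self) -> "IntentionCategory":
        expected = self.value is not Intention.full_acceptor
        if self.hesitant != expected:
            raise ValueError("hesitant must be true iff the category is not full_acceptor")
        return self


class Demographics(BaseModel):
    model_config = ConfigDict(frozen=True)

    pregnancy_status: Literal["pregnant", "postpartum"]
    baby_gender: Literal["female", "male", "unknown"] = "unknown"
    child_nickname: str = "your baby"
    child_age_days: Optional[int] = None
    maternal_age_years: float = 30.0

    @model_validator(mode="after")
    def _check(self) -> "Demographics":
        if (self.child_age_days is None) != (self.pregnancy_status == "pregnant"):
            raise ValueError("child_age_days must be null exactly when pregnant")
        if self.child_age_days is not None and self.child_age_days < 0:
            raise ValueError("child_age_days must be >= 0")
        return self


class ParticipantProfile(BaseModel):
    model_config = ConfigDict(frozen=True)

    participant_id: str
    domain_scores: DomainScores
    concern_scores: ConcernScores
    intention: IntentionCategory
    demographics: Demographics
    top3_ranking: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "ParticipantProfile":
        if len(self.top3_ranking) > 3:
            raise ValueError("top3_ranking holds at most 3 concerns")
        if len(set(self.top3_ranking)) != len(self.top3_ranking):
            raise ValueError("top3_ranking entries must be distinct")
        unknown = set(self.top3_ranking) - set(CONCERN_TOPICS)
        if unknown:
            raise ValueError(f"unknown concern ids in top3_ranking: {sorted(unknown)}")
        return self


# ---------------------------------------------------------------------------
# instrument loading


def _instrument_from_dict(raw: dict) -> InstrumentDefinition:
    kind = "value_domain" if raw["instrument_id"] == PVVS_ID else "concern_topic"
    coding = LikertCoding(
        n_levels=int(raw["coding"]["n_levels"]),
        labels=tuple(raw["coding"]["labels"]),
    )
    items = tuple(
        InstrumentItem(
            item_id=it["item_id"],
            group=it["group"],
            text=it.get("text", ""),
            polarity=it["polarity"],
            reverse_keyed=bool(it.get("reverse_keyed", False)),
        )
        for it in raw["items"]
    )
    return InstrumentDefinition(
        instrument_id=raw["instrument_id"],
        items=items,
        group_kind=kind,
        coding=coding,
        concern_labels=dict(raw.get("concern_labels", {})),
    )


def load_instrument(path: str | Path) -> InstrumentDefinition:
    """Load an instrument definition from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        return _instrument_from_dict(yaml.safe_load(fh))


def load_default_instruments() -> dict[str, InstrumentDefinition]:
    """Load the two instrument definitions shipped with the package."""
    out: dict[str, InstrumentDefinition] = {}
    pkg = resources.files("vaxtailor.data")
    for fname in ("pvvs_instrument.yaml", "beliefs_instrument.yaml"):
        raw = yaml.safe_load(pkg.joinpath(fname).read_text(encoding="utf-8"))
        inst = _instrument_from_dict(raw)
        out[inst.instrument_id] = inst
    return out


# ---------------------------------------------------------------------------
# scoring


def _group_means(
    record: ResponseRecord,
    instrument: InstrumentDefinition,
    policy: ScoringPolicy,
) -> dict[str, float]:
    unknown = set(record.answers) - set(instrument.item_ids)
    if unknown:
        raise SurveyValidationError(
            f"{record.participant_id}: unknown item ids for "
            f"{instrument.instrument_id}: {sorted(unknown)}"
        )
    n = instrument.coding.n_levels
    for item_id, code in record.answers.items():
        if not (1 <= code <= n):
            raise SurveyValidationError(
                f"{record.participant_id}: answer {code} for {item_id} "
                f"outside 1..{n}"
            )
    means: dict[str, float] = {}
    for group in instrument.group_ids:
        items = instrument.items_in_group(group)
        answered = [it for it in items if it.item_id in record.answers]
        if len(answered) < len(items):
            if not policy.allow_partial:
                raise SurveyValidationError(
                    f"{record.participant_id}: missing answers for group "
                    f"'{group}' ({len(answered)}/{len(items)} answered)"
                )
            if len(answered) < policy.min_fraction * len(items):
                raise SurveyValidationError(
                    f"{record.participant_id}: group '{group}' has fewer than "
                    f"{policy.min_fraction:.0%} of items answered"
                )
        codes = [instrument.oriented_code(it, record.answers[it.item_id]) for it in answered]
        means[group] = sum(codes) / len(codes)
    return means


def score_pvvs(
    record: ResponseRecord,
    instrument: InstrumentDefinition,
    policy: ScoringPolicy = ScoringPolicy(),
) -> DomainScores:
    """Score the values instrument: per-domain mean of oriented item codes."""
    if record.instrument_id != instrument.instrument_id:
        raise SurveyValidationError(
            f"record targets instrument '{record.instrument_id}', "
            f"not '{instrument.instrument_id}'"
        )
    if instrument.group_kind != "value_domain":
        raise SurveyValidationError("score_pvvs requires a value-domain instrument")
    return DomainScores(scores=_group_means(record, instrument, policy))


def score_concerns(
    record: ResponseRecord,
    instrument: InstrumentDefinition,
    policy: ScoringPolicy = ScoringPolicy(),
) -> ConcernScores:
    """Score the beliefs instrument.

    Single-item concerns pass the oriented code through; composite concerns
    take the mean of their member items.  Lower scores mean more anti-vaccine
    views.
    """
    if record.instrument_id != instrument.instrument_id:
        raise SurveyValidationError(
            f"record targets instrument '{record.instrument_id}', "
            f"not '{instrument.instrument_id}'"
        )
    if instrument.group_kind != "concern_topic":
        raise SurveyValidationError("score_concerns requires a concern-topic instrument")
    return ConcernScores(scores=_group_means(record, instrument, policy))


def classify_intention(count_response: str, timing_response: str) -> IntentionCategory:
    """Combine the two intention items into one of three groups.

    none/* -> refuses_all; all/on_time -> full_acceptor; every other
    combination (some vaccines, or all but later) -> alternative_schedule.
    Hesitant = refuser or alternative-scheduler.
    """
    counts = {"none", "some", "all"}
    timings = {"on_time", "later"}
    if count_response not in counts:
        raise SurveyValidationError(
            f"count response must be one of {sorted(counts)}, got {count_response!r}"
        )
    if timing_response not in timings:
        raise SurveyValidationError(
            f"timing response must be one of {sorted(timings)}, got {timing_response!r}"
        )
    if count_response == "none":
        cat = Intention.refuses_all
    elif count_response == "all" and timing_response == "on_time":
        cat = Intention.full_acceptor
    else:
        cat = Intention.alternative_schedule
    return IntentionCategory(value=cat, hesitant=cat is not Intention.full_acceptor)


def build_profile(
    participant_id: str,
    pvvs_record: ResponseRecord,
    beliefs_record: ResponseRecord,
    count_response: str,
    timing_response: str,
    demographics: Demographics,
    top3_ranking: tuple[str, ...] = (),
    instruments: Optional[dict[str, InstrumentDefinition]] = None,
    policy: ScoringPolicy = ScoringPolicy(),
) -> ParticipantProfile:
    """Score both instruments and assemble a complete participant profile."""
    instruments = instruments or load_default_instruments()
    return ParticipantProfile(
        participant_id=participant_id,
        domain_scores=score_pvvs(pvvs_record, instruments[PVVS_ID], policy),
        concern_scores=score_concerns(beliefs_record, instruments[BELIEFS_ID], policy),
        intention=classify_intention(count_response, timing_response),
        demographics=demographics,
        top3_ranking=tuple(top3_ranking),
    )
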