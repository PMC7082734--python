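"""Informational architecture, value-availability grid, and message templates.

The intervention's content is organised as 17 general topic areas split into
41 specific content areas, grouped under 6 standard home-page tiles; 4
specific areas were newly developed.  A separate grid records which of the
six value domains may frame each of the 13 Just-for-You tile topics
(tradition never may; the Kaiser-tips tile gets no values tailoring).
Messages are wrap-around introductions — a value-framed or untailored opening
sentence, an intention-matched sentence, and a demographic-rendered body —
around shared core content.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .constants import (
    CONCERN_TOPICS,
    DEFAULT_JFY_TILES,
    POSITIVE_REINFORCEMENT,
    STANDARD_TILES,
    VALUE_DOMAINS,
)
from .instruments import Demographics, Intention

__all__ = [
    "CatalogError",
    "ContentCatalog",
    "ValueAvailabilityMatrix",
    "MessageTemplate",
    "TemplateCatalog",
    "ValidationReport",
    "load_catalog",
    "load_value_matrix",
    "load_templates",
    "validate_catalog",
    "render_message",
]

_ALLOWED_PLACEHOLDERS = {
    "nickname",
    "pronoun_subject",
    "pronoun_object",
    "pronoun_possessive",
    "pregnancy_clause",
    "topic_title",
    "intro",
    "intention",
    "body",
}

_PRONOUNS = {
    "female": ("she", "her", "her"),
    "male": ("he", "him", "his"),
    "unknown": ("they", "them", "their"),
}


class CatalogError(ValueError):
    """Raised when catalog data violates the published architecture."""


def _placeholders(text: str) -> set[str]:
    return {
        field for _, field, _, _ in string.Formatter().parse(text) if field is not None
    }


# ---------------------------------------------------------------------------
# content catalog (topic architecture)


@dataclass(frozen=True)
class SpecificTopic:
    name: str
    newly_developed: bool = False


@dataclass(frozen=True)
class GeneralTopic:
    name: str
    tile: str
    specific_topics: tuple[SpecificTopic, ...]


@dataclass(frozen=True)
class ContentCatalog:
    general_topics: tuple[GeneralTopic, ...]
    concern_tile_map: dict[str, str]

    @property
    def specific_topics(self) -> tuple[SpecificTopic, ...]:
        return tuple(st for gt in self.general_topics for st in gt.specific_topics)

    @property
    def tiles(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for gt in self.general_topics:
            seen.setdefault(gt.tile, None)
        return tuple(seen)

    def standard_tile_for_concern(self, concern_id: str) -> str:
        try:
            return self.concern_tile_map[concern_id]
        except KeyError:
            raise CatalogError(f"no owning standard tile for concern '{concern_id}'") from None

    def to_dict(self) -> dict:
        return {
            "general_topics": [
                {
                    "name": gt.name,
                    "tile": gt.tile,
                    "specific_topics": [
                        {"name": st.name, "newly_developed": st.newly_developed}
                        for st in gt.specific_topics
                    ],
                }
                for gt in self.general_topics
            ],
            "concern_tile_map": dict(self.concern_tile_map),
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "ContentCatalog":
        generals = tuple(
            GeneralTopic(
                name=gt["name"],
                tile=gt["tile"],
                specific_topics=tuple(
                    SpecificTopic(
                        name=st["name"],
                        newly_developed=bool(st.get("newly_developed", False)),
                    )
                    for st in gt["specific_topics"]
                ),
            )
            for gt in raw["general_topics"]
        )
        return cls(general_topics=generals, concern_tile_map=dict(raw["concern_tile_map"]))


# ---------------------------------------------------------------------------
# value availability (13 Just-for-You topics x 6 values)


@dataclass(frozen=True)
class ValueAvailabilityMatrix:
    availability: dict[str, frozenset[str]]
    no_values_tailoring: frozenset[str]

    def __post_init__(self) -> None:
        if set(self.availability) != set(CONCERN_TOPICS):
            raise CatalogError("availability grid must cover exactly the 13 Just-for-You topics")
        for topic, values in self.availability.items():
            unknown = values - set(VALUE_DOMAINS)
            if unknown:
                raise CatalogError(f"unknown value ids for {topic}: {sorted(unknown)}")
            if "tradition" in values:
                raise CatalogError(f"tradition must be unavailable for every topic ({topic})")
        for topic in self.no_values_tailoring:
            if self.availability.get(topic):
                raise CatalogError(f"no-values-tailoring topic '{topic}' must have an empty row")

    def available(self, topic_id: str) -> frozenset[str]:
        if topic_id not in self.availability:
            # default tiles and the positive-reinforcement tile carry no
            # values framing by construction
            return frozenset()
        return self.availability[topic_id]


# ---------------------------------------------------------------------------
# message templates


@dataclass(frozen=True)
class MessageTemplate:
    topic_id: str
    value_id: Optional[str]  # None = untailored variant
    framing: str  # always "two_sided" in the shipped build
    intro: str
    published: bool  # True only for the verbatim published example intros


class TemplateCatalog:
    """The full message library, expanded so that every (topic, available
    value) cell and every topic's untailored variant has a template."""

    def __init__(self, raw: dict, matrix: ValueAvailabilityMatrix):
        self._raw = raw
        self.matrix = matrix
        self.wraparound: str = raw["wraparound"]
        self.default_body: str = raw["default_body"]
        self.intention_variants: dict[str, str] = dict(raw["generic_intention_variants"])
        self.titles: dict[str, str] = {}
        self.templates: dict[tuple[str, Optional[str]], MessageTemplate] = {}

        generic = raw["generic_value_intros"]
        for topic_id, spec in raw["topics"].items():
            self.titles[topic_id] = spec["title"]
            self.templates[(topic_id, None)] = MessageTemplate(
                topic_id=topic_id,
                value_id=None,
                framing="two_sided",
                intro=spec["untailored_intro"].strip(),
                published=False,
            )
            explicit = spec.get("value_intros", {})
            for value_id in sorted(matrix.available(topic_id)):
                if value_id in explicit:
                    intro, published = explicit[value_id].strip(), True
                else:
                    intro, published = generic[value_id].strip(), False
                self.templates[(topic_id, value_id)] = MessageTemplate(
                    topic_id=topic_id,
                    value_id=value_id,
                    framing="two_sided",
                    intro=intro,
                    published=published,
                )
        for tile_id, spec in raw["special_tiles"].items():
            self.titles[tile_id] = spec["title"]
            self.templates[(tile_id, None)] = MessageTemplate(
                topic_id=tile_id,
                value_id=None,
                framing="two_sided",
                intro=spec["intro"].strip(),
                published=False,
            )
        self.standard_tiles: dict[str, dict] = dict(raw["standard_tiles"])
        self.schedule_age_bands: dict = dict(raw["schedule_age_bands"])
        self._validate_placeholders()

    def _validate_placeholders(self) -> None:
        texts = [self.wraparound, self.default_body, *self.intention_variants.values()]
        texts += [t.intro for t in self.templates.values()]
        texts += [spec["blurb"] for spec in self.standard_tiles.values()]
        texts.append(self.schedule_age_bands["prenatal"])
        texts += [band["text"] for band in self.schedule_age_bands["bands"]]
        for text in texts:
            unknown = _placeholders(text) - _ALLOWED_PLACEHOLDERS
            if unknown:
                raise CatalogError(f"unknown placeholders {sorted(unknown)} in template: {text!r}")

    def get(self, topic_id: str, value_id: Optional[str]) -> MessageTemplate:
        try:
            return self.templates[(topic_id, value_id)]
        except KeyError:
            raise CatalogError(f"no template for topic={topic_id!r} value={value_id!r}") from None

    def title(self, topic_id: str) -> str:
        if topic_id in self.titles:
            return self.titles[topic_id]
        if topic_id in self.standard_tiles:
            return self.standard_tiles[topic_id]["title"]
        return topic_id.replace("_", " ").title()

    def schedule_text(self, demographics: Demographics) -> str:
        """Age-tailored vaccine-schedule sentence."""
        age = demographics.child_age_days
        if age is None:
            return self.schedule_age_bands["prenatal"]
        for band in self.schedule_age_bands["bands"]:
            if band["max_days"] is None or age <= band["max_days"]:
                return band["text"]
        return self.schedule_age_bands["bands"][-1]["text"]


# ---------------------------------------------------------------------------
# loading


def _read_yaml(name: str, override: Optional[str | Path]) -> dict:
    if override is not None:
        with open(override, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return yaml.safe_load(
        resources.files("vaxtailor.data").joinpath(name).read_text(encoding="utf-8")
    )


def load_catalog(path: Optional[str | Path] = None) -> ContentCatalog:
    return ContentCatalog.from_dict(_read_yaml("catalog.yaml", path))


def load_value_matrix(path: Optional[str | Path] = None) -> ValueAvailabilityMatrix:
    raw = _read_yaml("value_matrix.yaml", path)
    return ValueAvailabilityMatrix(
        availability={k: frozenset(v) for k, v in raw["availability"].items()},
        no_values_tailoring=frozenset(raw["no_values_tailoring"]),
    )


def load_templates(
    path: Optional[str | Path] = None,
    matrix: Optional[ValueAvailabilityMatrix] = None,
) -> TemplateCatalog:
    return TemplateCatalog(_read_yaml("templates.yaml", path), matrix or load_value_matrix())


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class ValidationReport:
    counts: dict[str, int]
    checks: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def validate_catalog(
    catalog: Optional[ContentCatalog] = None,
    matrix: Optional[ValueAvailabilityMatrix] = None,
    templates: Optional[TemplateCatalog] = None,
) -> ValidationReport:
    """Check the loaded content against the published architecture counts."""
    catalog = catalog or load_catalog()
    matrix = matrix or load_value_matrix()
    templates = templates or load_templates(matrix=matrix)

    n_general = len(catalog.general_topics)
    n_specific = len(catalog.specific_topics)
    n_new = sum(st.newly_developed for st in catalog.specific_topics)
    tiles = catalog.tiles
    tradition_rows = sum("tradition" in matrix.available(t) for t in CONCERN_TOPICS)

    template_cells_ok = True
    for topic in CONCERN_TOPICS:
        expected = {(topic, v) for v in matrix.available(topic)} | {(topic, None)}
        have = {key for key in templates.templates if key[0] == topic}
        if have != expected:
            template_cells_ok = False

    counts = {
        "general_topics": n_general,
        "specific_topics": n_specific,
        "standard_tiles": len(tiles),
        "newly_developed": n_new,
        "adapted": n_specific - n_new,
        "jfy_topics": len(matrix.availability),
        "tradition_available_rows": tradition_rows,
    }
    checks = {
        "general_topics_17": n_general == 17,
        "specific_topics_41": n_specific == 41,
        "standard_tiles_6": set(tiles) == set(STANDARD_TILES),
        "newly_developed_4": n_new == 4,
        "jfy_topics_13": len(matrix.availability) == 13,
        "tradition_never_available": tradition_rows == 0,
        "tips_tile_untailored": not matrix.available("tips_for_vaccinating_at_kaiser"),
        "templates_match_matrix": template_cells_ok,
        "concern_tiles_mapped": set(catalog.concern_tile_map) == set(CONCERN_TOPICS)
        and set(catalog.concern_tile_map.values()) <= set(STANDARD_TILES),
        "default_tiles_have_templates": all(
            (t, None) in templates.templates
            for t in (*DEFAULT_JFY_TILES, POSITIVE_REINFORCEMENT)
        ),
    }
    return ValidationReport(counts=counts, checks=checks)


# ---------------------------------------------------------------------------
# rendering


def _render_fields(demographics: Demographics, topic_title: str) -> dict[str, str]:
    subj, obj, poss = _PRONOUNS[demographics.baby_gender]
    if demographics.pregnancy_status == "pregnant":
        clause = " as you get ready for your baby's arrival"
    else:
        clause = f" as {demographics.child_nickname} grows"
    return {
        "nickname": demographics.child_nickname,
        "pronoun_subject": subj,
        "pronoun_object": obj,
        "pronoun_possessive": poss,
        "pregnancy_clause": clause,
        "topic_title": topic_title,
    }


def render_message(
    template: MessageTemplate,
    demographics: Demographics,
    templates: Optional[TemplateCatalog] = None,
    intention: Optional[Intention] = None,
) -> str:
    """Render a wrap-around message: intro + intention sentence + body.

    All placeholders are substituted from demographics; the output never
    contains residual ``{...}`` tokens (enforced by a final check).
    """
    templates = templates or load_templates()
    fields = _render_fields(demographics, templates.title(template.topic_id))
    intro = template.intro.format(**fields)
    intention_text = (
        templates.intention_variants[intention.value].format(**fields) if intention else ""
    )
    body = templates.default_body.format(**fields)
    message = templates.wraparound.format(intro=intro, intention=intention_text, body=body)
    message = " ".join(message.split())
    if _placeholders(message):
        raise CatalogError(f"unresolved placeholders remain in message: {message!r}")
    return message
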