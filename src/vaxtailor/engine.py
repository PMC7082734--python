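"""The tile-based tailoring engine.

Turns a scored participant profile into the 9-tile home page: three
Just-for-You (JFY) tiles carrying the most highly tailored content, and six
fixed standard tiles.  Concern topics scoring at or below 3 on the 1-5
belief scale qualify for tailoring; value domains scoring strictly above 2.5
on the 1-4 values scale are eligible to frame a message, subject to the
per-topic availability grid.  Within one assembly pass, a value already used
for an earlier tile is not reused until the topic's pool is exhausted, at
which point the pool resets (and the reset is logged).

All randomness flows through a named, seedable generator whose stream is
derived from (master seed, participant id, session index), so a layout is a
pure function of (profile, seed).
"""

from __future__ import annotations

import zlib
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .catalog import (
    ContentCatalog,
    TemplateCatalog,
    ValueAvailabilityMatrix,
    load_catalog,
    load_templates,
    load_value_matrix,
    render_message,
)
from .constants import (
    CONCERN_TOPICS,
    DEFAULT_JFY_TILES,
    N_HOME_TILES,
    N_JFY_TILES,
    POSITIVE_REINFORCEMENT,
    STANDARD_TILES,
)
from .instruments import (
    ConcernScores,
    DomainScores,
    IntentionCategory,
    ParticipantProfile,
)

__all__ = [
    "TailoringError",
    "TailoringConfig",
    "RotationState",
    "TileSpec",
    "HomePageLayout",
    "qualify_concerns",
    "select_jfy_topics",
    "eligible_values",
    "select_value",
    "assemble_home_page",
    "retailor",
]

MAX_SESSIONS = 4  # enrollment plus three retailorings


class TailoringError(ValueError):
    """Raised when tailoring preconditions are violated."""


class TailoringConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    concern_qualify_threshold: float = 3.0  # qualify if score <= threshold
    value_threshold: float = 2.5  # eligible if score > threshold (strict)
    default_tiles: tuple[str, ...] = DEFAULT_JFY_TILES
    n_jfy: int = N_JFY_TILES
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "TailoringConfig":
        if not (1.0 <= self.concern_qualify_threshold <= 5.0):
            raise ValueError("concern_qualify_threshold must lie in the 1-5 belief range")
        if not (1.0 <= self.value_threshold <= 4.0):
            raise ValueError("value_threshold must lie in the 1-4 values range")
        if len(self.default_tiles) < self.n_jfy - 1:
            raise ValueError("need enough default tiles to fill the JFY slots")
        return self


class RotationState(BaseModel):
    """Values consumed within the current tailoring pass."""

    used_values: list[str] = Field(default_factory=list)
    resets: int = 0


class TileSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    slot: str
    topic_id: str
    framing_value: Optional[str] = None
    message: str
    highlights: tuple[str, ...] = ()
    intention_variant: Optional[IntentionCategory] = None


class HomePageLayout(BaseModel):
    model_config = ConfigDict(frozen=True)

    participant_id: str
    session_index: int
    tiles: tuple[TileSpec, ...]
    audit_log: dict

    @model_validator(mode="after")
    def _check(self) -> "HomePageLayout":
        if len(self.tiles) != N_HOME_TILES:
            raise ValueError(f"home page must have exactly {N_HOME_TILES} tiles")
        if not (0 <= self.session_index < MAX_SESSIONS):
            raise ValueError("session_index must be in 0..3")
        return self

    @property
    def jfy_tiles(self) -> tuple[TileSpec, ...]:
        return self.tiles[:N_JFY_TILES]

    @property
    def standard_tiles(self) -> tuple[TileSpec, ...]:
        return self.tiles[N_JFY_TILES:]


# ---------------------------------------------------------------------------
# rule steps


def qualify_concerns(scores: ConcernScores, cfg: TailoringConfig) -> list[str]:
    """Concerns scoring at or below the threshold, most concerning first.

    Ties are broken by the canonical topic order for reproducibility.
    """
    hits = [c for c in CONCERN_TOPICS if scores[c] <= cfg.concern_qualify_threshold]
    return sorted(hits, key=lambda c: (scores[c], CONCERN_TOPICS.index(c)))


def select_jfy_topics(
    qualifying: list[str],
    top3_ranking: tuple[str, ...],
    cfg: TailoringConfig,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Assign the three Just-for-You topics.

    Returns ``(assignments, highlights)`` where each assignment is a
    ``(topic_id, mode)`` pair with mode one of ``concern``, ``default`` or
    ``positive_reinforcement``, and highlights are the qualifying concerns
    beyond the participant's top three (surfaced on standard tiles).

    More than three qualifying concerns require the participant's own top-3
    selection; the engine never auto-picks.
    """
    n = cfg.n_jfy
    if len(qualifying) > n:
        ranking = tuple(top3_ranking)
        if len(ranking) != n or len(set(ranking)) != n:
            raise TailoringError(
                f"{len(qualifying)} concerns qualify; a top-{n} selection by the "
                "participant is required"
            )
        stray = set(ranking) - set(qualifying)
        if stray:
            raise TailoringError(
                f"top-3 selection includes non-qualifying concerns: {sorted(stray)}"
            )
        assignments = [(c, "concern") for c in ranking]
        highlights = [c for c in qualifying if c not in ranking]
        return assignments, highlights

    assignments = [(c, "concern") for c in qualifying]
    if not qualifying:
        assignments.append((POSITIVE_REINFORCEMENT, "positive_reinforcement"))
    chosen = {t for t, _ in assignments}
    for default in cfg.default_tiles:
        if len(assignments) >= n:
            break
        if default in chosen:  # skip a default duplicating a chosen topic
            continue
        assignments.append((default, "default"))
        chosen.add(default)
    if len(assignments) < n:
        raise TailoringError("not enough default tiles to fill the JFY slots")
    return assignments, []


def eligible_values(
    topic_id: str,
    domains: DomainScores,
    matrix: ValueAvailabilityMatrix,
    cfg: TailoringConfig,
) -> frozenset[str]:
    """Values scored strictly above threshold and available for the topic."""
    endorsed = {v for v, s in domains.scores.items() if s > cfg.value_threshold}
    return frozenset(endorsed) & matrix.available(topic_id)


def select_value(
    topic_id: str,
    eligible: frozenset[str],
    state: RotationState,
    rng: np.random.Generator,
) -> tuple[Optional[str], bool]:
    """Uniform draw from the eligible pool, avoiding already-used values.

    When every eligible value has been used in an earlier topic, the pool is
    reset and the draw is taken from the full eligible set; the reset is
    reported in the second return slot.  An empty pool yields ``None`` (the
    untailored message is used).
    """
    pool = sorted(eligible)
    if not pool:
        return None, False
    unused = [v for v in pool if v not in state.used_values]
    reset = not unused
    if reset:
        state.resets += 1
        unused = pool
    choice = unused[int(rng.integers(len(unused)))]
    state.used_values.append(choice)
    return choice, reset


# ---------------------------------------------------------------------------
# assembly


def participant_rng(master_seed: int, participant_id: str) -> np.random.Generator:
    """One reproducible stream per participant assembly.

    The stream is a pure function of (master seed, participant id) and is
    restarted fresh for every home-page assembly, so a retailoring session
    with identical responses reproduces the identical layout.
    """
    pid_key = zlib.crc32(participant_id.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) % (2**31), pid_key])
    )


def assemble_home_page(
    profile: ParticipantProfile,
    catalog: Optional[ContentCatalog] = None,
    matrix: Optional[ValueAvailabilityMatrix] = None,
    templates: Optional[TemplateCatalog] = None,
    cfg: Optional[TailoringConfig] = None,
    session_index: int = 0,
) -> HomePageLayout:
    """Assemble the full 9-tile home page for one participant-session."""
    catalog = catalog or load_catalog()
    matrix = matrix or load_value_matrix()
    templates = templates or load_templates(matrix=matrix)
    cfg = cfg or TailoringConfig()
    if not (0 <= session_index < MAX_SESSIONS):
        raise TailoringError(
            f"session_index {session_index} outside the {MAX_SESSIONS}-exposure design"
        )

    rng = participant_rng(cfg.rng_seed, profile.participant_id)
    qualifying = qualify_concerns(profile.concern_scores, cfg)
    assignments, highlights = select_jfy_topics(qualifying, profile.top3_ranking, cfg)

    state = RotationState()
    audit: dict = {
        "master_seed": cfg.rng_seed,
        "participant_id": profile.participant_id,
        "session_index": session_index,
        "qualifying": {c: profile.concern_scores[c] for c in qualifying},
        "jfy": [],
        "highlights": list(highlights),
        "resets": 0,
    }

    tiles: list[TileSpec] = []
    for slot_idx, (topic_id, mode) in enumerate(assignments, start=1):
        if mode == "concern":
            pool = eligible_values(topic_id, profile.domain_scores, matrix, cfg)
            value, reset = select_value(topic_id, pool, state, rng)
        else:
            pool, value, reset = frozenset(), None, False
        template = templates.get(topic_id, value)
        message = render_message(
            template,
            profile.demographics,
            templates=templates,
            intention=profile.intention.value,
        )
        if topic_id == "the_vaccine_schedule":
            # the schedule tile is additionally tailored to the child's age
            age_text = templates.schedule_text(profile.demographics)
            message = f"{message} {_fill(age_text, profile, templates, topic_id)}"
        tiles.append(
            TileSpec(
                slot=f"jfy_{slot_idx}",
                topic_id=topic_id,
                framing_value=value,
                message=message,
                intention_variant=profile.intention,
            )
        )
        audit["jfy"].append(
            {
                "slot": f"jfy_{slot_idx}",
                "topic": topic_id,
                "mode": mode,
                "eligible_pool": sorted(pool),
                "chosen_value": value,
                "pool_reset": reset,
            }
        )
    audit["resets"] = state.resets

    tile_highlights: dict[str, list[str]] = {t: [] for t in STANDARD_TILES}
    for concern in highlights:
        tile_highlights[catalog.standard_tile_for_concern(concern)].append(concern)

    for idx, tile_id in enumerate(STANDARD_TILES, start=1):
        blurb = templates.standard_tiles[tile_id]["blurb"]
        message = _fill(blurb, profile, templates, tile_id)
        extra = tile_highlights[tile_id]
        if extra:
            names = ", ".join(templates.title(c) for c in extra)
            message = f"{message} Highlighted for you: {names}."
        tiles.append(
            TileSpec(
                slot=f"standard_{idx}",
                topic_id=tile_id,
                framing_value=None,
                message=message,
                highlights=tuple(extra),
                intention_variant=None,
            )
        )

    return HomePageLayout(
        participant_id=profile.participant_id,
        session_index=session_index,
        tiles=tuple(tiles),
        audit_log=audit,
    )


def _fill(text: str, profile: ParticipantProfile, templates: TemplateCatalog, topic_id: str) -> str:
    from .catalog import _render_fields  # shared placeholder resolution

    return " ".join(text.format(**_render_fields(profile.demographics, templates.title(topic_id))).split())


def retailor(
    profile: ParticipantProfile,
    session_index: int,
    catalog: Optional[ContentCatalog] = None,
    matrix: Optional[ValueAvailabilityMatrix] = None,
    templates: Optional[TemplateCatalog] = None,
    cfg: Optional[TailoringConfig] = None,
) -> HomePageLayout:
    """Re-tailor at a follow-up exposure (sessions 1-3).

    The layout is computed solely from the new session's freshly scored
    profile, with a fresh rotation state; the 9-tile structure is unchanged.
    """
    if not (1 <= session_index < MAX_SESSIONS):
        raise TailoringError(
            f"retailoring happens at sessions 1..{MAX_SESSIONS - 1}, got {session_index}"
        )
    return assemble_home_page(
        profile,
        catalog=catalog,
        matrix=matrix,
        templates=templates,
        cfg=cfg,
        session_index=session_index,
    )
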