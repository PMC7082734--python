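"""File schemas and the batch pipeline: responses in, layouts out.

Survey input is accepted as CSV (one row per participant-session; columns are
the item ids plus demographic, intention and top-3 fields) or JSON (one
response bundle per participant-session).  Output is JSON: one layout object
per participant-session, each carrying its tiles, rendered messages and the
full selection audit log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from pydantic import ValidationError

from .catalog import load_catalog, load_templates, load_value_matrix
from .constants import BELIEFS_ID, PVVS_ID
from .engine import HomePageLayout, TailoringConfig, assemble_home_page
from .instruments import (
    Demographics,
    ParticipantProfile,
    ResponseRecord,
    ScoringPolicy,
    SurveyValidationError,
    build_profile,
    load_default_instruments,
    load_instrument,
)

logger = logging.getLogger("vaxtailor")

__all__ = [
    "RunConfig",
    "PipelineResult",
    "read_responses",
    "run_pipeline",
    "layouts_to_json",
    "layouts_from_json",
]

_DEMO_FIELDS = (
    "pregnancy_status",
    "baby_gender",
    "child_nickname",
    "child_age_days",
    "maternal_age_years",
)


@dataclass(frozen=True)
class RunConfig:
    responses: str | Path
    out: Optional[str | Path] = None
    pvvs_instrument: Optional[str | Path] = None
    beliefs_instrument: Optional[str | Path] = None
    catalog: Optional[str | Path] = None
    value_matrix: Optional[str | Path] = None
    templates: Optional[str | Path] = None
    tailoring: TailoringConfig = field(default_factory=TailoringConfig)
    scoring: ScoringPolicy = field(default_factory=ScoringPolicy)
    fail_fast: bool = False
    log_level: str = "INFO"


@dataclass
class PipelineResult:
    layouts: list[HomePageLayout]
    errors: list[str]

    @property
    def exit_status(self) -> int:
        return 1 if self.errors else 0


def _row_to_profile(
    row: dict, row_no: int, instruments, policy: ScoringPolicy
) -> tuple[ParticipantProfile, int]:
    pid = str(row.get("participant_id", "")).strip()
    if not pid:
        raise SurveyValidationError(f"row {row_no}: missing participant_id")
    session = int(row.get("session_index", 0) or 0)

    def answers(instrument_id: str) -> dict[str, int]:
        inst = instruments[instrument_id]
        out = {}
        for item_id in inst.item_ids:
            if item_id in row and row[item_id] not in (None, ""):
                val = row[item_id]
                if pd.isna(val):
                    continue
                out[item_id] = int(val)
        return out

    age = row.get("child_age_days")
    age = None if age in (None, "") or pd.isna(age) else int(float(age))
    demo = Demographics(
        pregnancy_status=str(row["pregnancy_status"]),
        baby_gender=str(row.get("baby_gender", "unknown")),
        child_nickname=str(row.get("child_nickname") or "your baby"),
        child_age_days=age,
        maternal_age_years=float(row.get("maternal_age_years", 30.0) or 30.0),
    )
    raw_top3 = row.get("top3", "")
    if raw_top3 is None or (not isinstance(raw_top3, str) and pd.isna(raw_top3)):
        raw_top3 = ""
    top3 = tuple(t.strip() for t in str(raw_top3).split(";") if t.strip())

    profile = build_profile(
        participant_id=pid,
        pvvs_record=ResponseRecord(
            participant_id=pid,
            instrument_id=PVVS_ID,
            answers=answers(PVVS_ID),
            session_index=session,
        ),
        beliefs_record=ResponseRecord(
            participant_id=pid,
            instrument_id=BELIEFS_ID,
            answers=answers(BELIEFS_ID),
            session_index=session,
        ),
        count_response=str(row["intention_count"]),
        timing_response=str(row["intention_timing"]),
        demographics=demo,
        top3_ranking=top3,
        instruments=instruments,
        policy=policy,
    )
    return profile, session


def read_responses(
    path: str | Path,
    instruments=None,
    policy: ScoringPolicy = ScoringPolicy(),
    fail_fast: bool = False,
) -> tuple[list[tuple[ParticipantProfile, int]], list[str]]:
    """Read and score a CSV or JSON response file.

    Returns scored ``(profile, session_index)`` pairs and a list of
    row-addressed error messages for records that failed validation.
    """
    instruments = instruments or load_default_instruments()
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "r", encoding="utf-8") as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise SurveyValidationError("JSON responses must be a list of bundles")
        records = [_flatten_bundle(b) for b in rows]
    else:
        frame = pd.read_csv(path)
        records = frame.to_dict(orient="records")

    profiles: list[tuple[ParticipantProfile, int]] = []
    errors: list[str] = []
    for row_no, row in enumerate(records, start=1):
        try:
            profiles.append(_row_to_profile(row, row_no, instruments, policy))
        except (SurveyValidationError, ValidationError, KeyError, TypeError, ValueError) as exc:
            msg = f"row {row_no}: {exc}"
            if fail_fast:
                raise SurveyValidationError(msg) from exc
            errors.append(msg)
    return profiles, errors


def _flatten_bundle(bundle: dict) -> dict:
    row = {
        "participant_id": bundle.get("participant_id"),
        "session_index": bundle.get("session_index", 0),
        "intention_count": bundle.get("intention", {}).get("count"),
        "intention_timing": bundle.get("intention", {}).get("timing"),
        "top3": ";".join(bundle.get("top3", [])),
    }
    row.update(bundle.get("demographics", {}))
    row.update(bundle.get("pvvs_answers", {}))
    row.update(bundle.get("belief_answers", {}))
    return row


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Score responses, tailor every participant-session, write layouts."""
    logging.basicConfig(level=config.log_level)
    instruments = load_default_instruments()
    if config.pvvs_instrument:
        instruments[PVVS_ID] = load_instrument(config.pvvs_instrument)
    if config.beliefs_instrument:
        instruments[BELIEFS_ID] = load_instrument(config.beliefs_instrument)
    catalog = load_catalog(config.catalog)
    matrix = load_value_matrix(config.value_matrix)
    templates = load_templates(config.templates, matrix=matrix)

    profiles, errors = read_responses(
        config.responses, instruments, config.scoring, config.fail_fast
    )
    if not profiles and not errors:
        logger.warning("no response records found in %s", config.responses)

    layouts: list[HomePageLayout] = []
    for profile, session in profiles:
        try:
            layout = assemble_home_page(
                profile,
                catalog=catalog,
                matrix=matrix,
                templates=templates,
                cfg=config.tailoring,
                session_index=session,
            )
        except ValueError as exc:
            errors.append(f"participant {profile.participant_id}: {exc}")
            continue
        if layout.audit_log["resets"]:
            logger.warning(
                "participant %s: %d value-pool reset(s)",
                profile.participant_id,
                layout.audit_log["resets"],
            )
        logger.info(
            "participant %s session %d: jfy=%s",
            profile.participant_id,
            session,
            [t["topic"] for t in layout.audit_log["jfy"]],
        )
        layouts.append(layout)

    if config.out is not None:
        Path(config.out).write_text(layouts_to_json(layouts), encoding="utf-8")
    return PipelineResult(layouts=layouts, errors=errors)


def layouts_to_json(layouts: Sequence[HomePageLayout]) -> str:
    return json.dumps([json.loads(l.model_dump_json()) for l in layouts], indent=2)


def layouts_from_json(text: str) -> list[HomePageLayout]:
    """Deserialize layouts; schema mismatches name the offending field."""
    raw = json.loads(text)
    out = []
    for i, obj in enumerate(raw):
        try:
            out.append(HomePageLayout.model_validate(obj))
        except ValidationError as exc:
            missing = ", ".join(
                ".".join(str(p) for p in err["loc"]) for err in exc.errors()
            )
            raise SurveyValidationError(
                f"layout {i}: schema mismatch at field(s): {missing}"
            ) from exc
    return out
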