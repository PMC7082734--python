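"""Canonical identifiers shared across the package.

Every module refers to value domains, concern topics and home-page tiles by
these ids; the YAML data files are validated against them at load time.
"""

from __future__ import annotations

#: The six vaccine-value domains measured by the 20-item parental values scale.
VALUE_DOMAINS: tuple[str, ...] = (
    "security_disease_prevention",
    "security_vaccine_risk",
    "universalism",
    "self_direction",
    "conformity",
    "tradition",
)

#: The 13 belief/concern topics, named after the Just-for-You tile each one
#: feeds.  The first ten carry printed value-belief correlation targets; the
#: last three were added to the instrument later and have no targets.
CONCERN_TOPICS: tuple[str, ...] = (
    "vaccine_safety_research",
    "vaccine_preventable_diseases",
    "number_timing_of_vaccines",
    "immune_system_and_vaccines",
    "vaccine_side_effects",
    "do_own_research",
    "vaccine_ingredients",
    "vaccines_and_autism",
    "vaccination_risks_benefits",
    "alternative_delayed_schedules",
    "vaccines_during_pregnancy",
    "role_of_pharma",
    "tips_for_vaccinating_at_kaiser",
)

#: The six fixed standard tiles on the home page.
STANDARD_TILES: tuple[str, ...] = (
    "vaccine_schedule_timing",
    "vaccine_safety_side_effects",
    "how_vaccines_work",
    "reasons_to_vaccinate",
    "getting_vaccines_at_kaiser",
    "learn_more",
)

#: Default Just-for-You tiles used, in priority order, when a participant has
#: fewer than three qualifying concerns.
DEFAULT_JFY_TILES: tuple[str, ...] = (
    "the_vaccine_schedule",
    "baby_vaccine_visit",
    "kaiser_permanente_clinics",
)

#: Special first-tile topic for participants with no qualifying concerns.
POSITIVE_REINFORCEMENT: str = "positive_reinforcement"

#: Ids of the PVVS instrument and the beliefs instrument.
PVVS_ID = "pvvs"
BELIEFS_ID = "beliefs"

N_JFY_TILES = 3
N_STANDARD_TILES = 6
N_HOME_TILES = N_JFY_TILES + N_STANDARD_TILES
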