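"""Tailoring rules: qualification, tile selection, value rotation, assembly."""

import numpy as np
import pytest

from vaxtailor.constants import (
    CONCERN_TOPICS,
    DEFAULT_JFY_TILES,
    POSITIVE_REINFORCEMENT,
    STANDARD_TILES,
    VALUE_DOMAINS,
)
from vaxtailor.engine import (
    RotationState,
    TailoringError,
    assemble_home_page,
    eligible_values,
    qualify_concerns,
    retailor,
    select_jfy_topics,
    select_value,
)
from vaxtailor.instruments import ConcernScores, DomainScores

from conftest import make_profile, random_profile


def concerns_at(overrides=None, base=5.0):
    scores = {c: base for c in CONCERN_TOPICS}
    scores.update(overrides or {})
    return ConcernScores(scores=scores)


class TestQualifyConcerns:
    def test_score_exactly_three_qualifies(self, cfg):
        scores = concerns_at({"vaccines_and_autism": 3.0})
        assert qualify_concerns(scores, cfg) == ["vaccines_and_autism"]

    def test_no_concerns_when_all_high(self, cfg):
        assert qualify_concerns(concerns_at(), cfg) == []

    def test_matches_bruteforce_filter_and_orders_ascending(self, cfg):
        rng = np.random.default_rng(23)
        for _ in range(25):
            scores = concerns_at(
                {c: float(rng.integers(2, 11)) / 2 for c in CONCERN_TOPICS}
            )
            got = qualify_concerns(scores, cfg)
            expected = {c for c in CONCERN_TOPICS if scores[c] <= 3.0}
            assert set(got) == expected
            assert [scores[c] for c in got] == sorted(scores[c] for c in got)

    def test_equal_scores_tie_break_by_canonical_order(self, cfg):
        scores = concerns_at({"role_of_pharma": 2.0, "vaccine_safety_research": 2.0})
        got = qualify_concerns(scores, cfg)
        # vaccine_safety_research precedes role_of_pharma in the canonical list
        assert got == ["vaccine_safety_research", "role_of_pharma"]


class TestSelectJfyTopics:
    def test_no_concerns_gives_reinforcement_then_defaults(self, cfg):
        assignments, highlights = select_jfy_topics([], (), cfg)
        assert [t for t, _ in assignments] == [
            POSITIVE_REINFORCEMENT,
            "the_vaccine_schedule",
            "baby_vaccine_visit",
        ]
        assert assignments[0][1] == "positive_reinforcement"
        assert highlights == []

    def test_exactly_three_become_the_tiles(self, cfg):
        q = ["vaccines_and_autism", "vaccine_ingredients", "role_of_pharma"]
        assignments, highlights = select_jfy_topics(q, (), cfg)
        assert [t for t, _ in assignments] == q
        assert all(mode == "concern" for _, mode in assignments)
        assert highlights == []

    def test_one_or_two_concerns_padded_with_defaults_in_priority_order(self, cfg):
        assignments, _ = select_jfy_topics(["vaccine_side_effects"], (), cfg)
        assert [t for t, _ in assignments] == [
            "vaccine_side_effects",
            "the_vaccine_schedule",
            "baby_vaccine_visit",
        ]
        assignments, _ = select_jfy_topics(
            ["vaccine_side_effects", "vaccines_and_autism"], (), cfg
        )
        assert [t for t, _ in assignments] == [
            "vaccine_side_effects",
            "vaccines_and_autism",
            "the_vaccine_schedule",
        ]

    def test_duplicate_default_skipped(self, cfg):
        cfg2 = cfg.model_copy(
            update={"default_tiles": ("vaccine_side_effects", *DEFAULT_JFY_TILES)}
        )
        assignments, _ = select_jfy_topics(["vaccine_side_effects"], (), cfg2)
        assert [t for t, _ in assignments] == [
            "vaccine_side_effects",
            "the_vaccine_schedule",
            "baby_vaccine_visit",
        ]

    def test_more_than_three_uses_participant_ranking(self, cfg):
        q = ["c1", "c2", "c3", "c4", "c5"]
        q = [
            "vaccine_safety_research",
            "vaccine_side_effects",
            "vaccines_and_autism",
            "vaccine_ingredients",
            "role_of_pharma",
        ]
        ranking = ("vaccines_and_autism", "vaccine_safety_research", "role_of_pharma")
        assignments, highlights = select_jfy_topics(q, ranking, cfg)
        assert [t for t, _ in assignments] == list(ranking)
        assert highlights == ["vaccine_side_effects", "vaccine_ingredients"]

    def test_more_than_three_without_ranking_is_an_error(self, cfg):
        q = list(CONCERN_TOPICS[:5])
        with pytest.raises(TailoringError, match="top-3 selection"):
            select_jfy_topics(q, (), cfg)

    def test_ranking_outside_qualifying_is_an_error(self, cfg):
        q = list(CONCERN_TOPICS[:4])
        bad = ("vaccines_during_pregnancy", *CONCERN_TOPICS[:2])
        with pytest.raises(TailoringError, match="non-qualifying"):
            select_jfy_topics(q, bad, cfg)


class TestEligibleValues:
    def domains_at(self, overrides=None, base=1.0):
        scores = {d: base for d in VALUE_DOMAINS}
        scores.update(overrides or {})
        return DomainScores(scores=scores)

    def test_tradition_never_eligible(self, matrix, cfg):
        domains = self.domains_at({"tradition": 4.0})
        for topic in CONCERN_TOPICS:
            assert "tradition" not in eligible_values(topic, domains, matrix, cfg)

    def test_no_values_above_threshold_gives_empty_set(self, matrix, cfg):
        domains = self.domains_at(base=2.5)  # 2.5 does not exceed the threshold
        assert eligible_values("vaccine_side_effects", domains, matrix, cfg) == frozenset()

    def test_threshold_is_strict(self, matrix, cfg):
        domains = self.domains_at({"self_direction": 2.5, "security_vaccine_risk": 2.75})
        got = eligible_values("vaccine_side_effects", domains, matrix, cfg)
        assert got == frozenset({"security_vaccine_risk"})

    def test_side_effects_topic_with_all_values_endorsed(self, matrix, cfg):
        domains = self.domains_at(base=4.0)
        got = eligible_values("vaccine_side_effects", domains, matrix, cfg)
        assert got == frozenset(
            {"security_disease_prevention", "security_vaccine_risk", "self_direction"}
        )

    def test_untailored_topic_yields_empty_set(self, matrix, cfg):
        domains = self.domains_at(base=4.0)
        assert eligible_values(
            "tips_for_vaccinating_at_kaiser", domains, matrix, cfg
        ) == frozenset()


class TestSelectValue:
    def test_singleton_pool(self):
        rng = np.random.default_rng(0)
        state = RotationState()
        value, reset = select_value("t", frozenset({"conformity"}), state, rng)
        assert value == "conformity" and not reset
        assert state.used_values == ["conformity"]

    def test_exhausted_pool_resets_and_reuses(self):
        rng = np.random.default_rng(0)
        state = RotationState(used_values=["conformity"])
        value, reset = select_value("t", frozenset({"conformity"}), state, rng)
        assert value == "conformity" and reset
        assert state.resets == 1

    def test_empty_pool_gives_untailored(self):
        rng = np.random.default_rng(0)
        state = RotationState()
        value, reset = select_value("t", frozenset(), state, rng)
        assert value is None and not reset
        assert state.used_values == []

    def test_draws_are_uniform_over_the_pool(self):
        # chi-square against uniform over three values, 30,000 seeded draws
        rng = np.random.default_rng(1234)
        pool = frozenset({"universalism", "conformity", "self_direction"})
        counts = {v: 0 for v in pool}
        for _ in range(30_000):
            value, _ = select_value("t", pool, RotationState(), rng)
            counts[value] += 1
        expected = 10_000.0
        chi2 = sum((c - expected) ** 2 / expected for c in counts.values())
        # 99.9th percentile of chi-square with 2 df is 13.8
        assert chi2 < 13.8


class TestAssembly:
    def test_every_layout_has_nine_tiles(self, catalog, matrix, templates, cfg):
        layout = assemble_home_page(
            make_profile(), catalog=catalog, matrix=matrix, templates=templates, cfg=cfg
        )
        assert len(layout.tiles) == 9
        assert len(layout.jfy_tiles) == 3
        assert [t.topic_id for t in layout.standard_tiles] == list(STANDARD_TILES)

    def test_no_concerns_acceptor_gets_positive_reinforcement_first(
        self, catalog, matrix, templates, cfg
    ):
        layout = assemble_home_page(
            make_profile(count="all", timing="on_time"),
            catalog=catalog, matrix=matrix, templates=templates, cfg=cfg,
        )
        assert layout.tiles[0].topic_id == POSITIVE_REINFORCEMENT
        assert layout.tiles[0].framing_value is None

    def test_fixed_profile_and_seed_reproduce_byte_identical_layouts(
        self, catalog, matrix, templates, cfg
    ):
        profile = make_profile(
            domain_scores={d: 4.0 for d in VALUE_DOMAINS},
            concern_scores={"vaccines_and_autism": 2.0, "vaccine_ingredients": 2.5},
        )
        a = assemble_home_page(profile, catalog, matrix, templates, cfg)
        b = assemble_home_page(profile, catalog, matrix, templates, cfg)
        assert a.model_dump_json() == b.model_dump_json()

    def test_framing_values_satisfy_threshold_and_availability(
        self, catalog, matrix, templates, cfg
    ):
        rng = np.random.default_rng(99)
        for _ in range(40):
            profile = random_profile(rng)
            layout = assemble_home_page(profile, catalog, matrix, templates, cfg)
            assert len(layout.tiles) == 9
            for tile in layout.jfy_tiles:
                if tile.framing_value is not None:
                    assert profile.domain_scores[tile.framing_value] > cfg.value_threshold
                    assert tile.framing_value in matrix.available(tile.topic_id)

    def test_no_value_repeats_without_a_logged_reset(self, catalog, matrix, templates, cfg):
        rng = np.random.default_rng(7)
        for _ in range(40):
            profile = random_profile(rng)
            layout = assemble_home_page(profile, catalog, matrix, templates, cfg)
            chosen = [
                t["chosen_value"] for t in layout.audit_log["jfy"] if t["chosen_value"]
            ]
            if layout.audit_log["resets"] == 0:
                assert len(chosen) == len(set(chosen))

    def test_jfy_topics_come_from_the_allowed_universe(self, catalog, matrix, templates, cfg):
        rng = np.random.default_rng(41)
        allowed = set(CONCERN_TOPICS) | set(DEFAULT_JFY_TILES) | {POSITIVE_REINFORCEMENT}
        for _ in range(30):
            profile = random_profile(rng)
            layout = assemble_home_page(profile, catalog, matrix, templates, cfg)
            qualifying = set(layout.audit_log["qualifying"])
            for tile in layout.jfy_tiles:
                assert tile.topic_id in allowed
                if tile.topic_id in CONCERN_TOPICS:
                    assert tile.topic_id in qualifying

    def test_extra_concerns_highlighted_on_their_owning_tiles(
        self, catalog, matrix, templates, cfg
    ):
        profile = make_profile(
            concern_scores={
                "vaccines_and_autism": 1.0,
                "vaccine_ingredients": 1.5,
                "role_of_pharma": 2.0,
                "vaccine_side_effects": 2.5,
                "number_timing_of_vaccines": 3.0,
            },
            top3=("vaccines_and_autism", "vaccine_ingredients", "role_of_pharma"),
        )
        layout = assemble_home_page(profile, catalog, matrix, templates, cfg)
        by_tile = {t.topic_id: t for t in layout.standard_tiles}
        assert "vaccine_side_effects" in by_tile["vaccine_safety_side_effects"].highlights
        assert (
            "number_timing_of_vaccines" in by_tile["vaccine_schedule_timing"].highlights
        )

    def test_schedule_tile_text_tracks_child_age(self, catalog, matrix, templates, cfg):
        young = make_profile(child_age_days=30)
        older = make_profile(child_age_days=400)
        msg_young = assemble_home_page(young, catalog, matrix, templates, cfg).tiles[1]
        msg_older = assemble_home_page(older, catalog, matrix, templates, cfg).tiles[1]
        assert msg_young.topic_id == "the_vaccine_schedule"
        assert "2-month visit" in msg_young.message
        assert "toddler boosters" in msg_older.message


class TestRetailoring:
    def test_identical_responses_and_seed_reproduce_the_layout(
        self, catalog, matrix, templates, cfg
    ):
        profile = make_profile(
            domain_scores={d: 4.0 for d in VALUE_DOMAINS},
            concern_scores={"vaccines_and_autism": 2.0},
        )
        base = assemble_home_page(profile, catalog, matrix, templates, cfg, session_index=0)
        again = retailor(profile, 1, catalog, matrix, templates, cfg)
        assert [t.model_dump() for t in again.tiles] == [t.model_dump() for t in base.tiles]

    def test_resolved_concern_leaves_the_jfy_set(self, catalog, matrix, templates, cfg):
        worried = make_profile(concern_scores={"vaccines_and_autism": 2.0})
        relieved = make_profile(concern_scores={"vaccines_and_autism": 4.0})
        first = assemble_home_page(worried, catalog, matrix, templates, cfg)
        second = retailor(relieved, 1, catalog, matrix, templates, cfg)
        assert "vaccines_and_autism" in {t.topic_id for t in first.jfy_tiles}
        assert "vaccines_and_autism" not in {t.topic_id for t in second.jfy_tiles}

    def test_four_sessions_accepted_fifth_rejected(self, catalog, matrix, templates, cfg):
        profile = make_profile()
        for session in (1, 2, 3):
            retailor(profile, session, catalog, matrix, templates, cfg)
        with pytest.raises(TailoringError, match="sessions 1..3"):
            retailor(profile, 4, catalog, matrix, templates, cfg)
        with pytest.raises(TailoringError):
            retailor(profile, 0, catalog, matrix, templates, cfg)
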