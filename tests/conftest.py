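import numpy as np
import pytest

from vaxtailor.catalog import load_catalog, load_templates, load_value_matrix
from vaxtailor.constants import CONCERN_TOPICS, VALUE_DOMAINS
from vaxtailor.engine import TailoringConfig
from vaxtailor.instruments import (
    ConcernScores,
    Demographics,
    DomainScores,
    ParticipantProfile,
    classify_intention,
    load_default_instruments,
)


@pytest.fixture(scope="session")
def instruments():
    return load_default_instruments()


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def matrix():
    return load_value_matrix()


@pytest.fixture(scope="session")
def templates(matrix):
    return load_templates(matrix=matrix)


@pytest.fixture
def cfg():
    return TailoringConfig(rng_seed=7)


def make_profile(
    participant_id="p0",
    domain_scores=None,
    concern_scores=None,
    count="all",
    timing="on_time",
    top3=(),
    pregnancy_status="postpartum",
    child_age_days=45,
    baby_gender="female",
    nickname="Sam",
) -> ParticipantProfile:
    """Profile factory with pro-vaccine defaults (nothing qualifies)."""
    domains = {d: 3.0 for d in VALUE_DOMAINS}
    domains.update(domain_scores or {})
    concerns = {c: 5.0 for c in CONCERN_TOPICS}
    concerns.update(concern_scores or {})
    return ParticipantProfile(
        participant_id=participant_id,
        domain_scores=DomainScores(scores=domains),
        concern_scores=ConcernScores(scores=concerns),
        intention=classify_intention(count, timing),
        demographics=Demographics(
            pregnancy_status=pregnancy_status,
            baby_gender=baby_gender,
            child_nickname=nickname,
            child_age_days=child_age_days if pregnancy_status == "postpartum" else None,
        ),
        top3_ranking=top3,
    )


def random_profile(rng: np.random.Generator) -> ParticipantProfile:
    """Random valid profile exercising all tailoring branches."""
    domains = {d: float(rng.integers(4, 17)) / 4 for d in VALUE_DOMAINS}
    concerns = {c: float(rng.integers(2, 11)) / 2 for c in CONCERN_TOPICS}
    qualifying = [c for c in CONCERN_TOPICS if concerns[c] <= 3.0]
    top3 = ()
    if len(qualifying) > 3:
        picks = rng.choice(len(qualifying), size=3, replace=False)
        top3 = tuple(qualifying[i] for i in picks)
    count = ["none", "some", "all"][int(rng.integers(3))]
    timing = ["on_time", "later"][int(rng.integers(2))]
    pregnant = bool(rng.integers(2))
    return make_profile(
        participant_id=f"r{rng.integers(10**6)}",
        domain_scores=domains,
        concern_scores=concerns,
        count=count,
        timing=timing,
        top3=top3,
        pregnancy_status="pregnant" if pregnant else "postpartum",
        child_age_days=None if pregnant else int(rng.integers(0, 450)),
        baby_gender=["female", "male", "unknown"][int(rng.integers(3))],
    )
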