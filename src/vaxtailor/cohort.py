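"""Synthetic maternal survey cohorts with calibrated rank-correlation structure.

A Gaussian-copula generator: each value domain has a latent standard-normal
factor; domain items load on it with a per-domain loading that controls the
domain's internal consistency (Cronbach alpha); each belief/concern topic has
a latent factor written as a weighted sum of the six domain factors plus an
independent remainder.  Item latents are cut at thresholds derived from the
configured category marginals to produce 4-point value items and 5-point
belief items.

Discretization and domain-score averaging attenuate rank correlations, so
calibration is performed *post-discretization*: per-domain loadings are
bisected until the simulated Cronbach alpha matches its target, and each
(domain, concern) latent weight is bisected until the simulated Spearman
correlation between the observed domain score and the observed concern score
matches its target.  Bisection uses common random numbers from a fixed
calibration seed, independent of the cohort seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.optimize import brentq
from scipy.stats import norm

from .constants import BELIEFS_ID, CONCERN_TOPICS, PVVS_ID, VALUE_DOMAINS
from .instruments import (
    Demographics,
    InstrumentDefinition,
    ParticipantProfile,
    ResponseRecord,
    build_profile,
    load_default_instruments,
)
from .psychometrics import cronbach_alpha, spearman_pvalue, spearman_rho

__all__ = [
    "CohortSpec",
    "LatentModel",
    "Cohort",
    "CohortReport",
    "InfeasibleTargetError",
    "default_spec",
    "calibrate_latent",
    "generate_cohort",
    "cohort_report",
]

#: Concern topics with published correlation targets (the other three were
#: added to the instrument after the correlation analysis).
TARGETED_CONCERNS: tuple[str, ...] = CONCERN_TOPICS[:10]

_MAX_ROW_NORM_SQ = 0.999


class InfeasibleTargetError(ValueError):
    """A rank-correlation target is unattainable under the given marginals."""


class CohortSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    n: int = 1000
    seed: int = 0
    target_spearman: dict[str, dict[str, float]]
    alpha_targets: dict[str, float]
    within_domain_loading: Optional[dict[str, float]] = None
    value_item_marginals: tuple[float, ...]
    belief_item_marginals: tuple[float, ...]
    composite_item_loading: float = 0.85
    intention_mixture: dict[str, float]
    demographics: dict
    calibration: dict

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for probs, levels in ((self.value_item_marginals, 4), (self.belief_item_marginals, 5)):
            if len(probs) != levels:
                raise ValueError(f"marginals must have {levels} categories")
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) <= 0:
                raise ValueError("marginal probabilities must be positive and sum to 1")
        if abs(sum(self.intention_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("intention mixture must sum to 1")
        for concern, row in self.target_spearman.items():
            if concern not in CONCERN_TOPICS:
                raise ValueError(f"unknown concern in targets: {concern}")
            for domain, r in row.items():
                if domain not in VALUE_DOMAINS:
                    raise ValueError(f"unknown value domain in targets: {domain}")
                if not (-1.0 < r < 1.0):
                    raise ValueError(f"target |r| must be < 1 ({concern}/{domain}={r})")
        if set(self.alpha_targets) != set(VALUE_DOMAINS):
            raise ValueError("alpha targets must cover the six value domains")
        return self


def default_spec(**overrides) -> CohortSpec:
    """The shipped default cohort configuration, with optional overrides."""
    raw = yaml.safe_load(
        resources.files("vaxtailor.data")
        .joinpath("cohort_defaults.yaml")
        .read_text(encoding="utf-8")
    )
    raw.setdefault("n", 1000)
    raw.setdefault("seed", 0)
    raw["value_item_marginals"] = tuple(raw["value_item_marginals"])
    raw["belief_item_marginals"] = tuple(raw["belief_item_marginals"])
    raw.update(overrides)
    return CohortSpec(**raw)


@dataclass(frozen=True)
class LatentModel:
    """Calibrated parameters of the copula generator."""

    loadings: dict[str, float]  # per-domain item loading on the domain factor
    belief_weights: np.ndarray  # (13 concerns x 6 domains) latent weights
    value_thresholds: np.ndarray  # 3 cut points for 4-level items
    belief_thresholds: np.ndarray  # 4 cut points for 5-level items
    composite_item_loading: float
    warnings_log: tuple[str, ...] = field(default=())


# ---------------------------------------------------------------------------
# structural helpers


def _thresholds(probs) -> np.ndarray:
    return norm.ppf(np.cumsum(probs)[:-1])


def _discretize(z: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    return np.searchsorted(cuts, z) + 1


def _domain_item_counts(instruments: dict[str, InstrumentDefinition]) -> dict[str, int]:
    pvvs = instruments[PVVS_ID]
    return {d: len(pvvs.items_in_group(d)) for d in VALUE_DOMAINS}


def _concern_item_counts(instruments: dict[str, InstrumentDefinition]) -> dict[str, int]:
    beliefs = instruments[BELIEFS_ID]
    return {c: len(beliefs.items_in_group(c)) for c in CONCERN_TOPICS}


# ---------------------------------------------------------------------------
# calibration


def _simulate_domain_items(
    loading: float, f: np.ndarray, eps: np.ndarray, cuts: np.ndarray
) -> np.ndarray:
    """Discretized item codes for one domain given its factor and item noise."""
    lam = float(loading)
    latent = lam * f[:, None] + np.sqrt(1.0 - lam * lam) * eps
    return _discretize(latent, cuts)


def _simulate_concern_score(
    c: float,
    f: np.ndarray,
    zeta: np.ndarray,
    nu: Optional[np.ndarray],
    mu: float,
    cuts: np.ndarray,
) -> np.ndarray:
    """Observed concern score for a latent weight ``c`` on one domain factor.

    Contributions of the other five factors are independent of this factor,
    so for pairwise calibration they can be absorbed into the remainder
    ``zeta`` without changing the pair's joint distribution.
    """
    g = c * f + np.sqrt(1.0 - c * c) * zeta
    if nu is None:  # single-item concern
        return _discretize(g, cuts).astype(float)
    item_latent = mu * g[:, None] + np.sqrt(1.0 - mu * mu) * nu
    return _discretize(item_latent, cuts).mean(axis=1)


def _calibrate_loading(
    target_alpha: float,
    k: int,
    f: np.ndarray,
    eps: np.ndarray,
    cuts: np.ndarray,
    tol: float,
) -> float:
    def objective(lam: float) -> float:
        items = _simulate_domain_items(lam, f, eps, cuts)
        return cronbach_alpha(items.astype(float)) - target_alpha

    lo, hi = 0.05, 0.995
    if objective(hi) < 0:
        return hi
    if objective(lo) > 0:
        return lo
    return float(brentq(objective, lo, hi, xtol=tol))


def calibrate_latent(
    spec: CohortSpec,
    instruments: Optional[dict[str, InstrumentDefinition]] = None,
) -> LatentModel:
    """Calibrate loadings and latent weights to the configured targets.

    Raises :class:`InfeasibleTargetError` when a pairwise target exceeds the
    attainable post-discretization bound.  If a concern's calibrated weight
    vector has squared norm above 1 (the six-factor decomposition cannot
    reproduce all its targets jointly), the row is rescaled onto the feasible
    boundary and a warning is logged — the analog of a nearest-PSD repair.
    """
    instruments = instruments or load_default_instruments()
    k_domain = _domain_item_counts(instruments)
    k_concern = _concern_item_counts(instruments)
    cal = spec.calibration
    n = int(cal.get("n", 60000))
    tol = float(cal.get("tol", 0.0015))
    rng = np.random.default_rng(int(cal.get("seed", 20200305)))

    value_cuts = _thresholds(spec.value_item_marginals)
    belief_cuts = _thresholds(spec.belief_item_marginals)

    # common random numbers, shared across all bisection evaluations
    f = rng.standard_normal(n)
    eps = {d: rng.standard_normal((n, k_domain[d])) for d in VALUE_DOMAINS}
    zeta = rng.standard_normal(n)
    nu = rng.standard_normal((n, 2))

    log: list[str] = []

    loadings: dict[str, float] = {}
    for d in VALUE_DOMAINS:
        if spec.within_domain_loading and d in spec.within_domain_loading:
            loadings[d] = float(spec.within_domain_loading[d])
        else:
            loadings[d] = _calibrate_loading(
                spec.alpha_targets[d], k_domain[d], f, eps[d], value_cuts, tol
            )

    domain_scores = {
        d: _simulate_domain_items(loadings[d], f, eps[d], value_cuts).mean(axis=1)
        for d in VALUE_DOMAINS
    }

    weights = np.zeros((len(CONCERN_TOPICS), len(VALUE_DOMAINS)))
    for j, concern in enumerate(CONCERN_TOPICS):
        row_targets = spec.target_spearman.get(concern, {})
        composite = k_concern[concern] > 1
        nu_j = nu if composite else None
        mu = spec.composite_item_loading
        for didx, domain in enumerate(VALUE_DOMAINS):
            target = float(row_targets.get(domain, 0.0))
            if target == 0.0:
                continue  # independence maps to independence

            score_d = domain_scores[domain]

            def objective(c: float) -> float:
                concern_score = _simulate_concern_score(
                    c, f, zeta, nu_j, mu, belief_cuts
                )
                return spearman_rho(score_d, concern_score) - target

            c_max = 0.9999
            hi_val = objective(c_max) + target  # attainable upper bound
            lo_val = objective(-c_max) + target  # attainable lower bound
            if not (lo_val < target < hi_val):
                raise InfeasibleTargetError(
                    f"target {target:+.3f} for ({domain}, {concern}) is outside "
                    f"the attainable range [{lo_val:+.3f}, {hi_val:+.3f}] "
                    "under the configured marginals"
                )
            weights[j, didx] = float(brentq(objective, -c_max, c_max, xtol=tol))

        norm_sq = float(np.sum(weights[j] ** 2))
        if norm_sq > _MAX_ROW_NORM_SQ:
            scale = np.sqrt(_MAX_ROW_NORM_SQ / norm_sq)
            weights[j] *= scale
            msg = (
                f"concern '{concern}': joint latent weights overshoot the unit "
                f"sphere (|w|^2={norm_sq:.3f}); rescaled by {scale:.3f} — its "
                "realized correlations will fall slightly below target"
            )
            log.append(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)

    return LatentModel(
        loadings=loadings,
        belief_weights=weights,
        value_thresholds=value_cuts,
        belief_thresholds=belief_cuts,
        composite_item_loading=spec.composite_item_loading,
        warnings_log=tuple(log),
    )


_CAL_CACHE: dict[str, LatentModel] = {}


def calibrated_model(spec: CohortSpec, instruments=None) -> LatentModel:
    """Memoized calibration (the calibration itself is deterministic)."""
    key = spec.model_copy(update={"n": 0, "seed": 0}).model_dump_json()
    if key not in _CAL_CACHE:
        _CAL_CACHE[key] = calibrate_latent(spec, instruments)
    return _CAL_CACHE[key]


# ---------------------------------------------------------------------------
# generation


_INTENTION_ANSWERS = {
    # category -> possible (count, timing) survey answers
    "refuses_all": (("none", "on_time"), ("none", "later")),
    "alternative_schedule": (("some", "on_time"), ("some", "later"), ("all", "later")),
    "full_acceptor": (("all", "on_time"),),
}


@dataclass
class Cohort:
    """A generated cohort: one row per participant, survey-schema columns."""

    data: pd.DataFrame
    spec: CohortSpec
    model: LatentModel
    instruments: dict[str, InstrumentDefinition]

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def profiles(self) -> Iterator[ParticipantProfile]:
        """Score every participant through the survey-model pipeline."""
        pvvs_ids = self.instruments[PVVS_ID].item_ids
        bel_ids = self.instruments[BELIEFS_ID].item_ids
        for _, row in self.data.iterrows():
            demo = Demographics(
                pregnancy_status=row["pregnancy_status"],
                baby_gender=row["baby_gender"],
                child_nickname=row["child_nickname"],
                child_age_days=None if pd.isna(row["child_age_days"]) else int(row["child_age_days"]),
                maternal_age_years=float(row["maternal_age_years"]),
            )
            top3 = tuple(t for t in str(row["top3"]).split(";") if t) if row["top3"] else ()
            yield build_profile(
                participant_id=row["participant_id"],
                pvvs_record=ResponseRecord(
                    participant_id=row["participant_id"],
                    instrument_id=PVVS_ID,
                    answers={i: int(row[i]) for i in pvvs_ids},
                ),
                beliefs_record=ResponseRecord(
                    participant_id=row["participant_id"],
                    instrument_id=BELIEFS_ID,
                    answers={i: int(row[i]) for i in bel_ids},
                ),
                count_response=row["intention_count"],
                timing_response=row["intention_timing"],
                demographics=demo,
                top3_ranking=top3,
                instruments=self.instruments,
            )


def generate_cohort(
    spec: CohortSpec,
    model: Optional[LatentModel] = None,
    instruments: Optional[dict[str, InstrumentDefinition]] = None,
) -> Cohort:
    """Draw a full synthetic cohort under the calibrated latent model."""
    instruments = instruments or load_default_instruments()
    model = model or calibrated_model(spec, instruments)
    rng = np.random.default_rng(np.random.SeedSequence(int(spec.seed) % (2**31)))
    n = spec.n
    pvvs = instruments[PVVS_ID]
    beliefs = instruments[BELIEFS_ID]

    cols: dict[str, np.ndarray | list] = {}
    cols["participant_id"] = [f"p{idx:06d}" for idx in range(n)]

    factors = rng.standard_normal((n, len(VALUE_DOMAINS)))
    for didx, domain in enumerate(VALUE_DOMAINS):
        items = pvvs.items_in_group(domain)
        lam = model.loadings[domain]
        eps = rng.standard_normal((n, len(items)))
        codes = _discretize(
            lam * factors[:, didx : didx + 1] + np.sqrt(1 - lam * lam) * eps,
            model.value_thresholds,
        )
        for col, item in enumerate(items):
            cols[item.item_id] = codes[:, col]

    concern_scores = np.empty((n, len(CONCERN_TOPICS)))
    for j, concern in enumerate(CONCERN_TOPICS):
        w = model.belief_weights[j]
        resid_sd = np.sqrt(max(0.0, 1.0 - float(w @ w)))
        g = factors @ w + resid_sd * rng.standard_normal(n)
        items = beliefs.items_in_group(concern)
        if len(items) == 1:
            codes = _discretize(g[:, None], model.belief_thresholds)
        else:
            mu = model.composite_item_loading
            nu = rng.standard_normal((n, len(items)))
            codes = _discretize(
                mu * g[:, None] + np.sqrt(1 - mu * mu) * nu, model.belief_thresholds
            )
        for col, item in enumerate(items):
            cols[item.item_id] = codes[:, col]
        concern_scores[:, j] = codes.mean(axis=1)

    # intention draws from the mixture, mapped back to raw survey answers
    categories = list(spec.intention_mixture)
    probs = np.array([spec.intention_mixture[c] for c in categories])
    cat_idx = rng.choice(len(categories), size=n, p=probs)
    counts, timings = [], []
    for idx in cat_idx:
        options = _INTENTION_ANSWERS[categories[idx]]
        count, timing = options[int(rng.integers(len(options)))]
        counts.append(count)
        timings.append(timing)
    cols["intention_count"] = counts
    cols["intention_timing"] = timings

    # demographics
    demo = spec.demographics
    pregnant = rng.random(n) < float(demo["pregnant_fraction"])
    genders = list(demo["gender_probs"])
    gprobs = np.array([demo["gender_probs"][g] for g in genders])
    cols["pregnancy_status"] = np.where(pregnant, "pregnant", "postpartum")
    cols["baby_gender"] = [genders[i] for i in rng.choice(len(genders), size=n, p=gprobs)]
    nick = list(demo["nicknames"])
    cols["child_nickname"] = [nick[i] for i in rng.integers(len(nick), size=n)]
    ages = rng.integers(0, int(demo["child_age_days_max"]) + 1, size=n).astype(float)
    ages[pregnant] = np.nan
    cols["child_age_days"] = ages
    cols["maternal_age_years"] = np.clip(
        rng.normal(float(demo["maternal_age_mean"]), float(demo["maternal_age_sd"]), size=n),
        18.0,
        45.0,
    ).round(1)

    # participant top-3 selection, simulated as the three most pressing
    # (lowest-scoring) qualifying concerns, random tie-breaking via jitter
    jitter = rng.random((n, len(CONCERN_TOPICS))) * 1e-6
    order = np.argsort(concern_scores + jitter, axis=1)
    needs_top3 = (concern_scores <= 3.0).sum(axis=1) > 3
    top3_col = [""] * n
    for i in np.flatnonzero(needs_top3):
        top3_col[i] = ";".join(CONCERN_TOPICS[j] for j in order[i, :3])
    cols["top3"] = top3_col
    cols["session_index"] = np.zeros(n, dtype=int)

    return Cohort(data=pd.DataFrame(cols), spec=spec, model=model, instruments=instruments)


# ---------------------------------------------------------------------------
# reporting


@dataclass(frozen=True)
class CohortReport:
    spearman: pd.DataFrame  # 6 value domains x 10 targeted concerns
    spearman_full: pd.DataFrame  # 6 x 13
    pvalues: pd.DataFrame
    alphas: dict[str, float]
    intention_counts: dict[str, int]


def domain_score_frame(cohort: Cohort) -> pd.DataFrame:
    """Vectorized per-domain mean scores (identical arithmetic to the
    survey-model scoring path; verified against it in the tests)."""
    pvvs = cohort.instruments[PVVS_ID]
    out = {}
    for d in VALUE_DOMAINS:
        ids = [it.item_id for it in pvvs.items_in_group(d)]
        out[d] = cohort.data[ids].mean(axis=1)
    return pd.DataFrame(out)


def concern_score_frame(cohort: Cohort) -> pd.DataFrame:
    beliefs = cohort.instruments[BELIEFS_ID]
    out = {}
    for c in CONCERN_TOPICS:
        ids = [it.item_id for it in beliefs.items_in_group(c)]
        out[c] = cohort.data[ids].mean(axis=1)
    return pd.DataFrame(out)


def cohort_report(cohort: Cohort) -> CohortReport:
    """Summarize a cohort: value-belief Spearman matrix, domain alphas,
    intention-group counts, with t-approximation p-value annotations."""
    dscores = domain_score_frame(cohort)
    cscores = concern_score_frame(cohort)
    n = len(cohort)

    rho = pd.DataFrame(index=list(VALUE_DOMAINS), columns=list(CONCERN_TOPICS), dtype=float)
    pval = rho.copy()
    for d in VALUE_DOMAINS:
        for c in CONCERN_TOPICS:
            r = spearman_rho(dscores[d].to_numpy(), cscores[c].to_numpy())
            rho.loc[d, c] = r
            pval.loc[d, c] = spearman_pvalue(r, n)

    pvvs = cohort.instruments[PVVS_ID]
    alphas = {}
    for d in VALUE_DOMAINS:
        ids = [it.item_id for it in pvvs.items_in_group(d)]
        alphas[d] = cronbach_alpha(cohort.data[ids].to_numpy(dtype=float))

    from .instruments import classify_intention

    counts: dict[str, int] = {"refuses_all": 0, "alternative_schedule": 0, "full_acceptor": 0}
    for count, timing in zip(cohort.data["intention_count"], cohort.data["intention_timing"]):
        counts[classify_intention(count, timing).value.value] += 1

    return CohortReport(
        spearman=rho[list(TARGETED_CONCERNS)],
        spearman_full=rho,
        pvalues=pval,
        alphas=alphas,
        intention_counts=counts,
    )
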