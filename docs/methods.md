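# Methods

This note documents the models and procedures implemented in `vaxtailor`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the design choices made where the published description of
the intervention leaves the design open.

## Survey model

**Coding.** Both instruments are coded `strongly_disagree = 1` …
`strongly_agree = n` (n = 4 for values, 5 for beliefs). The published
description gives the response anchors but not the numeric direction; this
direction is chosen so that, with pro-vaccine-worded belief items, *lower*
concern scores mean *more* anti-vaccine views — the orientation the
qualifying rule depends on. Items worded against vaccination are declared
`anti_vaccine` (or `reverse_keyed`) in the instrument YAML and reversed as
`n + 1 − code` before averaging. The shipped defaults mark every item
positively keyed, since no keying information was published.

**Structure.** The values instrument has 20 items over six domains, split
4/3/4/3/3/3 (security—disease prevention, security—vaccine risk,
universalism, self-direction, conformity, tradition). The beliefs instrument
has 13 concern topics, three of them two-item composites (16 items). Which
topics are composite, the item wording, and which three topics were later
additions were never published; the shipped YAML is an explicit synthetic
default preserving all published structural counts, and both instruments are
user-overridable files. Domain and concern scores are plain arithmetic means
of (oriented) item codes; composites average their members.

**Missing data.** The default policy rejects a record with any missing item
in a scored group. With `ScoringPolicy(allow_partial=True)` a group mean is
taken over answered items when at least 50% of the group's items were
answered. The conservative default reflects that no imputation rule was
published.

**Intention.** `none/*` → refuses all; `all/on_time` → full acceptor; the
remaining combinations (`some/*`, `all/later`) → alternative schedule.
Hesitant ≡ not full acceptor. The mapping is total over the six answer
pairs and its image has exactly three categories.

## Psychometrics

Implemented from first principles (the statistics libraries are used only as
independent cross-checks in the tests):

- **Cronbach alpha**: `k/(k−1) · (1 − Σ s²ᵢ / s²_total)` with sample
  variances (ddof = 1). Zero total-score variance returns NaN with a
  `RuntimeWarning` rather than raising — the degenerate case is data, not a
  programming error.
- **Spearman correlation**: Pearson correlation of mid-ranks; ties receive
  the mean rank of their block, the standard choice for heavily tied Likert
  data. Constant vectors return a flagged NaN. A two-sided t-approximation
  p-value is available for annotating synthetic correlation tables only; no
  selection decision in the engine uses it.
- **SUS**: standard scoring — odd items contribute `code − 1`, even items
  `5 − code`, the sum scaled by 2.5 onto 0–100. The published usability
  assessment cites the instrument's 0–100 range and the passable-70
  threshold, which fix this convention.

## Tailoring engine

**Thresholds.** A concern *qualifies* when its score is ≤ 3.0 on the 1–5
scale (inclusive boundary: "3 or less"). A value is *eligible* when its
domain score is > 2.5 on the 1–4 scale (strict: "exceeding 2.5"). Both are
`TailoringConfig` fields with these defaults.

**JFY selection.** More than three qualifying concerns require the
participant's own top-3 ranking (the engine refuses to auto-pick); exactly
three become the tiles; one or two are padded with the default tiles in
priority order (The Vaccine Schedule, Baby Vaccine Visit, Kaiser Permanente
Clinics), skipping a default that would duplicate a chosen topic; zero
qualifying concerns put a positive-reinforcement tile first. Qualifying
concerns beyond the top three become highlights on the standard tile that
owns the topic. Qualifying concerns are ordered ascending by score with ties
broken by the canonical 13-topic order, for reproducibility.

**Value rotation.** For each concern tile, the eligible pool is the
intersection of endorsed values and the topic's row in the availability grid
(tradition is available nowhere; the Kaiser-tips topic has no values
tailoring). One value is drawn uniformly from the pool minus the values
already used on this page; an exhausted pool resets (drawing from the full
pool) and the reset is logged at WARNING and recorded in the audit log.
Rotation state is scoped to a single page assembly and cleared between
sessions.

**Randomness.** Each assembly uses a fresh `numpy` generator seeded by
(master seed, CRC-32 of the participant id). The stream deliberately does
*not* include the session index: a retailoring session with responses
identical to an earlier session reproduces the identical tiles, and the
layout is a pure function of (profile, seed). Four exposures (session 0 plus
three retailorings) are accepted; a fifth is rejected.

**Demographic tailoring.** Messages substitute the child's nickname,
pronouns (she/he with a neutral *they* fallback for unknown gender), and a
pregnancy-status clause; the vaccine-schedule tile selects an age-band
sentence from the child's age in days (prenatal, ≤ 60, ≤ 120, ≤ 180, ≤ 365,
older).

**Templates.** Six value-framed introduction sentences are the published
examples (the alternative-schedules and do-own-research topics for the two
security domains and self-direction); every other intro, body, and
intention-variant sentence is synthetic filler written in the same two-sided
style and marked as such in the data files. Only two framing variants exist
at runtime — two-sided values-framed and two-sided untailored — because the
published design rejected 1-sided/push/pull framings.

## Synthetic cohort generator

**Model.** Six independent standard-normal domain factors `F_d`. Value item
`i` in domain `d` has latent `λ_d F_d + √(1−λ_d²) ε_i`; each concern topic
`j` has latent factor `G_j = Σ_d w_jd F_d + √(1−Σ w²) η_j`; composite
concern items load on `G_j` with a fixed within-concern loading (0.85).
Latents are cut at thresholds `Φ⁻¹(cumulative marginals)` to produce 4- and
5-level codes.

**Calibration is post-discretization** — the module's central engineering
point. Discretization and domain-score averaging attenuate rank
correlations, so matching targets on the latent scale would systematically
undershoot. Instead, with common random numbers from a fixed calibration
seed (60,000 draws):

1. each `λ_d` is bisected until the simulated Cronbach alpha of the domain's
   discretized items hits the published target (.74/.73/.86/.66/.62/.79);
2. each `w_jd` with a nonzero target is bisected until the simulated
   Spearman between the observed domain score and the observed concern score
   hits the published correlation-table value. Because the factors are
   independent, the pair's joint law depends only on `(w_jd, λ_d,
   thresholds)`, so per-pair bisection is exact; a zero target maps to a
   zero weight.

A pairwise target outside the attainable post-discretization range raises an
error naming the pair and the bound. If a concern's calibrated weight vector
leaves the unit sphere — the six-factor decomposition cannot reproduce all
six of its targets jointly — the row is rescaled onto the feasible boundary
with a logged warning (the analog of a nearest-PSD repair). With the shipped
defaults this happens for two of the ten targeted concerns
(vaccination-risks-benefits and alternative-delayed-schedules), whose
realized correlations land ~0.02–0.03 below target; all other pairs recover
within Monte-Carlo noise.

**Defaults.** Category marginals are mildly right-skewed pro-vaccine
(values: 0.08/0.17/0.40/0.35; beliefs: 0.05/0.10/0.20/0.35/0.30), chosen as
realistic for an insured US maternal population — the real marginals were
never published, so these are stand-ins, not estimates. Intention mixture
0.05/0.15/0.80 (refuser/alternative/acceptor). The three later-added
concerns have zero correlation targets by default (none were published),
overridable in the `CohortSpec`. Demographics (pregnancy status, gender, nickname,
child age, maternal age) are drawn independently of the survey scores.

**What passing tests show.** The generator reproduces the *published
second-order structure* (rank correlations, reliabilities) and marginal
shapes, under seed-deterministic sampling. It does not model value–belief
nonlinearity, demographic covariance with attitudes, longitudinal belief
drift across the four exposures (sessions are resampled independently), or
the survey's true marginals and sample size. Tests passing on synthetic
cohorts therefore validate the engine's rules and the statistics pipeline,
not claims about any real population.

**Problem sizes.** The shipped checks use n = 20,000 for correlation
recovery (Monte-Carlo s.e. ≈ 0.006, comfortably inside the ±0.02 band),
n = 5,000 for reliability recovery (±0.03 band), and 60,000 calibration
draws (bisection tolerance 0.0015); the recovery-scaling property uses
n ∈ {500; 5,000; 50,000} with a handful of replicates. These sizes make the
whole suite run in well under a minute while keeping every tolerance
dominated by the quantity under test rather than simulation noise.

## Known limitations

- Item wording, composite membership, the concern→tile correspondence, and
  the three later-added topics are synthetic defaults behind config files;
  real instrument data would slot in by replacing the YAML.
- The two boundary-rescaled concern rows under-recover their printed
  correlations by design (see above); a model with correlated value factors
  could close the gap at the cost of inventing an unpublished
  factor-covariance structure.
- The engine renders plain-text messages; visual/HTML presentation,
  infographics, and the untailored control site are out of scope (the
  control shares the same catalog minus tailored components).
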