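# vaxtailor

A values-tailored vaccine-messaging engine for maternal vaccine-hesitancy
interventions: survey scoring, a tile-based message-tailoring algorithm with
value rotation, a validated content catalog, and a Gaussian-copula synthetic
cohort generator calibrated to published value–belief rank correlations.

## The problem

Parental vaccine hesitancy drives under-vaccination of infants. Web-based
tailored messaging addresses it by matching content to each mother's measured
beliefs — and, more novelly, by *framing* that content around the personal
values she endorses. This package implements the tailoring engine behind such
an intervention:

- **Values** are measured with a 20-item scale covering six domains
  (security—disease prevention, security—vaccine risk, universalism,
  self-direction, conformity, tradition) on a 4-point agreement scale; each
  domain score is the mean of its items.
- **Beliefs/concerns** cover 13 topics on a 5-point scale (some topics are
  two-item composites), oriented so lower scores mean more anti-vaccine
  views. A topic scoring **≤ 3** is a *qualifying concern*.
- **Intention to vaccinate** combines two items (how many of the infant-series
  vaccines; on time vs. later) into three groups: refuses all, alternative
  schedule, full acceptor. The first two define *vaccine-hesitant*.

The home page always has **9 tiles**: three *Just for You* (JFY) tiles
carrying the most tailored content, and six fixed standard tiles. The JFY
tiles are the participant's top three qualifying concerns (her own ranking if
more than three qualify); with fewer than three, default tiles fill in by
priority (*The Vaccine Schedule*, *Baby Vaccine Visit*, *Kaiser Permanente
Clinics*), and with none, the first tile gives positive reinforcement. Each
concern tile opens with a value-framed sentence: among the values scored
**> 2.5** and available for that topic (a 13 × 6 availability grid; tradition
is never available), one is drawn uniformly at random, never repeating within
a page until the topic's pool is exhausted (then the pool resets, logged).
Extra qualifying concerns are highlighted on their owning standard tiles;
messages render the child's nickname, pronouns, pregnancy status and age.

Because no participant-level data are deposited, the package ships a
**synthetic cohort generator**: a Gaussian copula whose per-domain item
loadings are bisected to the published Cronbach alphas
(.74/.73/.86/.66/.62/.79) and whose latent value–belief weights are bisected
so the *post-discretization* Spearman correlations match the published 6 × 10
correlation table (e.g. self-direction × do-own-research = 0.505).

## Worked example

```python
import vaxtailor as vt

profile = vt.ParticipantProfile(
    participant_id="demo",
    domain_scores=vt.DomainScores(scores={
        "security_disease_prevention": 3.5, "security_vaccine_risk": 3.0,
        "universalism": 2.25, "self_direction": 3.67,
        "conformity": 2.0, "tradition": 3.33,
    }),
    concern_scores=vt.ConcernScores(scores={
        **{c: 4.5 for c in vt.CONCERN_TOPICS},
        "alternative_delayed_schedules": 2.5,
        "vaccine_side_effects": 3.0,
    }),
    intention=vt.classify_intention("all", "later"),   # alternative schedule
    demographics=vt.Demographics(
        pregnancy_status="postpartum", baby_gender="male",
        child_nickname="Sam", child_age_days=50,
    ),
)
layout = vt.assemble_home_page(profile, cfg=vt.TailoringConfig(rng_seed=7))
print("qualifying:", layout.audit_log["qualifying"])
for tile in layout.jfy_tiles:
    print(f"{tile.slot}: {tile.topic_id}  [value: {tile.framing_value}]")
```

prints

```
qualifying: {'alternative_delayed_schedules': 2.5, 'vaccine_side_effects': 3.0}
jfy_1: alternative_delayed_schedules  [value: security_vaccine_risk]
jfy_2: vaccine_side_effects  [value: self_direction]
jfy_3: the_vaccine_schedule  [value: None]
```

Two concerns qualify (2.5 and 3.0 are at or below the 3.0 cutoff; the 3.0
boundary is inclusive), so they take the first two JFY slots in ascending
score order and the highest-priority default tile fills the third. The first
tile's message opens with the security—vaccine-risk framing sentence drawn
from the topic's eligible pool — the three values scored above 2.5 that the
availability grid permits for alternative/delayed schedules — and continues
with the alternative-schedule intention variant and the demographic-rendered
body ("That's a lot of needles (and a lot of tears)! You want to protect
your child. …"). The layout is a pure function of (profile, seed): rerunning
with `rng_seed=7` reproduces it byte for byte.

The same flows are scriptable from the shell:

```bash
vaxtailor cohort generate --n 500 --seed 1 --out cohort.csv
vaxtailor tailor run --responses cohort.csv --seed 1 --out layouts.json
vaxtailor catalog validate
```

## Layout

- `src/vaxtailor/instruments.py` — instrument definitions, scoring, intention
- `src/vaxtailor/psychometrics.py` — Cronbach alpha, Spearman (mid-rank ties), SUS
- `src/vaxtailor/catalog.py` — content architecture, availability grid, templates
- `src/vaxtailor/engine.py` — the tailoring algorithm and page assembly
- `src/vaxtailor/cohort.py` — calibrated Gaussian-copula cohort generator
- `src/vaxtailor/pipeline.py`, `cli.py` — file schemas, batch runs, CLI
- `src/vaxtailor/data/*.yaml` — instruments, catalog, availability, templates,
  generator defaults (synthetic placeholder wording is marked as such)
- `docs/methods.md` — models, calibration details, design choices, limitations
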