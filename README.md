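# suitescore

Scoring, classification and agreement analysis for behavioural
suitability testing of dogs in animal-assisted services (AAI/AAS).

Teams that certify therapy dogs face a recurring problem: caregivers'
expectations about their own dog are poorly calibrated, and behavioural
test protocols need reproducible scoring rules rather than purely
holistic judgment. `suitescore` implements a complete analysis pipeline
for a valence–arousal ("circumplex") test battery:

* **Scoring model** — two independent evaluators place each of 24 test
  sub-phases (room exploration, food motivation, sounds, handling by
  strangers, …) on a Cartesian grid: valence *x* ∈ [−5, +5] (withdrawal
  → approach) and arousal *y* ∈ [−5, +5] (calm → agitated). Aggression
  forces a score of (−5, +5); refusal to participate forces *x* = −5.
* **Suitability classifier** — a suitable dog's scores fall in the
  closed triangle with vertices (0, 0), (+5, +3), (+5, −3), i.e.
  {(x, y) : 0 ≤ x ≤ 5, |y| ≤ 0.6·x}. A fixed priority cascade maps a
  dog's score sheet to **S** (suitable), **P** (pending suitability) or
  **U** (unsuitable): aggression → U; refusal-grade valence in a
  critical sub-phase → U; majority of scores inside the triangle → S,
  demoted to P by high-arousal episodes (y > +3 at positive valence) or
  wary critical sub-phases; majority outside → U. Every decision
  carries a machine-readable rationale.
* **Questionnaire scoring** — seven C-BARQ-derived sections (frequency
  or intensity scales) plus the caregiver's open-ended verdict, mapped
  to an expected class (Yes → S, No → U, Maybe / "Yes after a training
  programme" → P).
* **Agreement analysis** — caregiver-vs-test 3×3 contingency,
  unweighted Cohen's κ = (p₀ − pₑ)/(1 − pₑ), per-class and overall
  concordance, and two-rater reliability via the intraclass correlation
  ICC(3,1) over all pooled (dyad, sub-phase) scores.
* **Nonparametric battery** — Kruskal–Wallis with rank
  η² = (H − k + 1)/(n − k), Dunn pairwise z tests with Holm step-down
  adjustment, Mann–Whitney U with r = |z|/√n, paired Wilcoxon for
  pre/post salivary cortisol, and a Shapiro–Wilk normality gate.
* **Synthetic cohorts** — a seeded generator emulating a 38-dyad study
  (latent classes 9 : 5 : 24, half-grid scores, two noisy raters,
  questionnaire section effects, null cortisol deltas, miscalibrated
  caregiver verdicts) so that the whole pipeline is testable without
  any private data.

## Worked example

Simulate a cohort, classify it, and run the full report:

```sh
suitescore simulate --seed 2 --n-dyads 10 --out cohort
suitescore classify cohort/scores.csv --out classes.json
```

```
dyad001: U  (R7:inside fraction 0.375 <= 0.5 with non-negative median valence; borderline policy -> U)
dyad005: U  (R7:inside fraction 0.208 <= 0.5 with non-negative median valence; borderline policy -> U)
dyad006: U  (R1:aggression in b)
dyad008: P  (R5:negative valence in critical sub-phase e)
...
```

Each line is one dog–caregiver dyad: the class and the decision rule
that fired — e.g. dyad006 showed aggression in the food-motivation
sub-phase, and dyad008 was wary during the sounds sub-phase, demoting
it from S to P.

The same stages are available as library calls. Recomputing the
caregiver-vs-test agreement from the published 38-dyad verdict table:

```python
from suitescore import build_contingency, cohens_kappa, map_open_ended
from suitescore.datasets import published_agreement_pairs

categories, test_classes = published_agreement_pairs()
expected = [map_open_ended(c) for c in categories]
result = cohens_kappa(build_contingency(expected, test_classes))
print(round(result.kappa, 3), result.label)   # 0.285 fair
```

The agreement stage reports κ = 0.285 ("fair"), row concordances
40.9 / 20.0 / 90.9 % and overall concordance 52.6 % — caregivers rate
most unsuitable dogs as suitable, while almost never calling a suitable
dog unsuitable.

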