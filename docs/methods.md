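# Methods

## The scoring model

Each dog–caregiver dyad undergoes a 26-sub-phase behavioural test; the
24 sub-phases `a`–`x` are scored, the final two use a separate grid and
are outside this package's scope. Two evaluators independently place
every sub-phase on a valence–arousal plane: valence *x* ∈ [−5, +5]
(withdrawal/refusal/aggression → approach/tolerance) and arousal
*y* ∈ [−5, +5] (activation level, independent of valence). Scores are
accepted as any real in range; in practice evaluators work on a
half-point grid, and the synthetic generator emits exactly that grid.
Two behavioural events override the coordinate: aggression is always
recorded as (−5, +5), and refusal to participate fixes valence at −5.
The refusal override deliberately leaves arousal as observed, because
only the valence assignment is prescribed; a dog may refuse calmly or
frantically, and that information is worth keeping.

The protocol does not prescribe how two raters' sheets become one
classification, so aggregation is configurable; the default consensus
is the per-sub-phase arithmetic mean with flags OR'd across raters and
overrides re-applied afterwards, so that a flagged sub-phase can never
average away. Missing sub-phases are tolerated and reported — all
downstream fractions are over *scored* sub-phases, never over 24.

## The suitability region and decision cascade

The admissible pattern for a suitable dog is positive valence with an
arousal band that widens as valence grows: the closed triangle with
vertices (0, 0), (+5, +3), (+5, −3), i.e. {(x, y) : 0 ≤ x ≤ 5,
|y| ≤ 0.6·x}. The loosely stated vertices are fixed to exact
coordinates and the boundary is closed so the origin and edges classify
reproducibly; membership is evaluated as `5·|y| ≤ 3·x`, which is exact
in binary floating point for all half-grid scores.

The decision cascade runs in fixed priority order (first match wins):

1. any aggression event → U;
2. refusal-grade valence (−5) in a critical sub-phase → U;
3. food exemption: every sub-phase inside except food motivation
   (`b`), median valence > 0 → S (low food drive alone is not
   disqualifying);
4. majority inside (strictly more than half), no high-arousal episode,
   no critical sub-phase with negative valence → S;
5. majority inside, but episodes or wary critical sub-phases → P;
6. majority outside with negative median valence → U;
7. majority outside with non-negative median valence → the borderline
   policy (default U, configurable to P).

A *high-arousal episode* is arousal strictly above the region's +3 cap
at positive valence — the jumping-on-a-stranger pattern; one episode
(k = 1) suffices to demote S to P. The *critical set* defaults to
{d, e, f, m, q, u}: unusual objects, sounds, and handling by strangers
and groups, the sub-phases most diagnostic for AAI work. The borderline
default of U reflects the observed practice that dogs with mostly
out-of-region scores were rated unsuitable even at non-negative median
valence (the unsuitable group's published median valence is +1).

All thresholds live in `ClassificationConfig` and every result records
which rule fired.

## Agreement statistics

Caregiver-vs-test agreement uses the unweighted Cohen's κ on the 3×3
S/P/U table — the published value is reproduced exactly only by the
unweighted form — plus per-row concordance (100·diagonal/row total) and
overall concordance (100·trace/N). Landis–Koch bands are attached as
labels only.

Inter-rater reliability is the intraclass correlation over all pooled
(dyad, sub-phase) scores, one dimension at a time. The variant is not
identifiable from the published report; the default is the two-way
consistency single-rater form, ICC(3,1) (pingouin's ICC(C,1)), chosen
because the tightness of the published confidence intervals implies
pooling all ~900 sub-phase scores, and the model descriptor is always
surfaced in the output. Exact reproduction of the published 0.605/0.699
would require the raw two-rater sheets, which are private.

## Nonparametric battery

All group comparisons are rank-based with average ranks and variance
tie-correction throughout. Kruskal–Wallis effect size is the rank
eta-squared η² = (H − k + 1)/(n − k), which reproduces every published
section value from the printed H at k = 3, n = 38 (including the
negative −0.0186) and can be slightly negative under the null. Dunn
pairwise z statistics are computed on pooled ranks with the
tie-corrected standard error; Holm's step-down adjustment is delegated
to statsmodels. Mann–Whitney reports r = |z|/√n from the tie-corrected
normal approximation without continuity correction; on the published
U = 25.5 (14 vs 24) this gives 0.70 against a published 0.71, the gap
attributable to tie handling in the original ranks. The paired Wilcoxon
reports V (sum of positive-difference ranks) with zero differences
dropped. Magnitude bands are fixed at 0.01/0.06/0.14 for η² and
0.1/0.3/0.5 for r; the published tables label effect sizes
inconsistently, so the bands here are this package's own convention and
are reported next to every value. The Shapiro–Wilk gate documents why
the nonparametric path is justified; it never switches methods
silently. Group statistics operate on per-dyad medians (n = 38), the
scale on which U = 25.5 is possible (max 14 × 24 = 336); pooled
per-score mode exists only for descriptives.

## Synthetic cohort generator

The generator emulates the structure of a 38-dyad validation study:

* latent classes S/P/U with probabilities 9/38, 5/38, 24/38;
* per-class (valence, arousal) means/SDs of (2.5/1.0, 1.0/1.3),
  (2.1/1.2, 1.2/1.7), (0.4/2.2, 1.5/1.8) — truncated normals clipped to
  [−5, 5] and snapped to the half-grid, moment-matched to the published
  per-class score statistics;
* two rater sheets per dyad: latent score + independent N(0, 1.5²)
  rater error, re-snapped. With the default class mix this puts the
  pooled valence ICC near 0.66–0.69 analytically
  (σ²ᵦ/(σ²ᵦ + σ²ₑ), see `expected_icc`), between the published
  arousal (0.605) and valence (0.699) reliabilities;
* per-sub-phase aggression probability 0.01 and refusal probability
  0.02 for latent-U dogs only;
* questionnaire sections with the published S+P vs U moments for
  separation, attachment, fear/anxiety and aggression; the
  non-significant sections are class-independent at plausible
  ordinal-scale levels (trainability 2.9 ± 0.7, excitability 1.9 ± 0.9,
  other 0.8 ± 0.6). The generator emits one aggregate value per
  section: the item-level composition is not identifiable from
  section-level group moments, so it is not simulated;
* cortisol as a log-normal matched to the published overall moments
  (mean 1.580, SD 1.396 ng/mL), decomposed into a per-dog level and
  independent per-time residuals so the T1 − T0 delta is symmetric
  about zero with no class effect (the published outcome); 3/38 of
  pairs are missing, mirroring swab failures;
* a caregiver verdict drawn conditionally on the latent class with the
  column-normalized probabilities of the published caregiver-vs-test
  contingency table, making the emergent κ ≈ 0.285 a property of the
  generator, not an input constant. Caregiver-P verdicts split
  "Maybe" : "Yes after a training programme" 3 : 2;
* one expected missing score per ~900 (both raters), matching the one
  observed gap in the published score counts.

Scores are independent across sub-phases given the class by default;
an equicorrelation knob adds a shared per-dog component if within-dog
correlation is wanted. Flags are shared by both raters — evaluator
disagreement about the *occurrence* of aggression is not modelled,
only about coordinates.

### What passing tests do and do not show

The generator reproduces marginal moments, not real behavioural
structure: no carryover between sub-phases, no sub-phase-specific
difficulty, no evaluator drift. Tests that pass on synthetic cohorts
demonstrate that the pipeline's statistics are computed correctly and
are well calibrated under the stated model, not that the behavioural
test itself is valid.

### Latent-group recovery

Under the default configuration the classifier recovers the latent
S∪P-vs-U split for ≈76–80 % of dyads (100-seed average), not the ≥90 %
one might hope for. This is a property of the stated study conditions,
not a fixable code path: with the published per-class score moments, a
latent-P dog's per-sub-phase probability of landing inside the triangle
is only ≈0.45 (≈0.33 after two-rater noise), so the strict-majority
rule assigns most latent-P dogs to U, and latent-S dogs sit near 0.55.
Even classifying noise-free latent sheets tops out near 87 %. The
corresponding acceptance test asserts the 90 % bound and is expected to
fail; the honest measured value is reported by `scripts/acceptance.py`
as `latent_group_recovery_pct`. Latent-U dogs are recovered essentially
perfectly, which is the clinically conservative direction.

## Numerical choices

* Region membership via integer-exact `5·|y| ≤ 3·x`; no epsilon.
* Quartiles by linear interpolation (the convention that makes
  quarter-point quartiles attainable from half-grid scores).
* Grid snapping rounds to the nearest half point with banker's
  rounding at exact quarter points (numpy convention).
* Degenerate inputs: empty sheets, all-missing sections, constant
  samples and degenerate contingency tables raise informative errors;
  all-tied group comparisons return the null (H = 0, p = 1) rather
  than failing inside a pipeline run.
* Holm adjustment and rank tests delegate to statsmodels/scipy; Dunn's
  z and Cohen's κ are computed directly from their defining formulas
  and are cross-checked in the test suite against independent routes
  (hand-computed ranks, scikit-learn's κ).

## Problem sizes

The test suite and the acceptance script use 100 synthetic cohorts of
38 dyads for recovery/ICC/κ averages, 200 replicates for the Wilcoxon
type-I calibration, and the full 441-point half-grid lattice for the
region-membership oracle — sizes at which Monte-Carlo error is well
below the asserted tolerances while a full run stays in the
tens-of-seconds range.

## Known limitations

* Per-dog reproduction of the published classification is impossible:
  the raw sheets are private and the published rule is partly holistic
  ("evaluators assessed each case individually").
* The ICC variant and the two-group effect-size formula used in two of
  the published tables are not identifiable; the package documents its
  own choices instead of guessing.
* The questionnaire module expects verdicts already simplified to the
  four controlled categories; it does no free-text processing.
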