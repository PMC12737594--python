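import json

import numpy as np
import pytest

from suitescore.group_stats import mann_whitney
from suitescore.score_model import SubPhase
from suitescore.synthetic import (
    Cohort,
    GeneratorConfig,
    cohort_to_files,
    generate_cohort,
    rater_score_matrix,
)


class TestGenerateCohort:
    def test_counts(self, default_cohort):
        cohort, truth = default_cohort
        assert len(cohort) == 38
        assert len(truth) == 38
        rows = sum(
            sheet.n_scored for d in cohort.dyads for sheet in d.rater_sheets
        )
        assert rows <= 38 * 24 * 2
        assert rows >= 38 * 24 * 2 - 2 * 24  # missingness is rare

    def test_degenerate_class_probabilities(self):
        cohort, truth = generate_cohort(
            GeneratorConfig(n_dyads=10, class_probs=(1.0, 0.0, 0.0)), seed=1
        )
        assert set(truth.values()) == {"S"}

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GeneratorConfig(class_probs=(0.5, 0.5, 0.5))

    def test_scores_on_half_grid_in_range(self, default_cohort):
        cohort, _ = default_cohort
        for d in cohort.dyads:
            for sheet in d.rater_sheets:
                for s in sheet.scores.values():
                    assert -5 <= s.valence <= 5 and -5 <= s.arousal <= 5
                    assert (2 * s.valence) == int(2 * s.valence)
                    assert (2 * s.arousal) == int(2 * s.arousal)

    def test_flagged_scores_carry_overrides(self, default_cohort):
        cohort, _ = default_cohort
        for d in cohort.dyads:
            for s in d.consensus.scores.values():
                if s.aggression:
                    assert (s.valence, s.arousal) == (-5, 5)
                elif s.refusal:
                    assert s.valence == -5

    def test_latent_labels_separate_from_observables(self, default_cohort):
        cohort, truth = default_cohort
        assert set(truth.values()) <= {"S", "P", "U"}
        for d in cohort.dyads:
            assert not hasattr(d, "latent_class")

    def test_suitable_pooled_valence_mean_near_target(self):
        # CLT bound: ~216 suitable-class scores with SD ~1 under default
        # proportions; the pooled mean should land within 2.5 +/- 0.25.
        means = []
        for seed in range(5):
            cohort, truth = generate_cohort(seed=seed)
            pooled = [
                s.valence
                for d in cohort.dyads
                if truth[d.dyad_id] == "S"
                for s in d.consensus.scores.values()
            ]
            means.append(np.mean(pooled))
        assert abs(np.mean(means) - 2.5) <= 0.25

    def test_separation_section_difference_detected_in_most_seeds(self):
        # the generator encodes a real S+P vs U separation-score gap; at
        # n = 38 the Mann-Whitney test should reject in most cohorts.
        rejections = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cohort, truth = generate_cohort(seed=seed)
            sp = [
                d.questionnaire.section_score("separation")
                for d in cohort.dyads
                if truth[d.dyad_id] in ("S", "P")
            ]
            u = [
                d.questionnaire.section_score("separation")
                for d in cohort.dyads
                if truth[d.dyad_id] == "U"
            ]
            if sp and u and mann_whitney(u, sp).p < 0.05:
                rejections += 1
        assert rejections > n_seeds / 2

    def test_caregiver_verdicts_show_fair_agreement_with_latent_class(self):
        # the verdict matrix makes a kappa near 0.29 between caregiver
        # expectation and latent class an emergent property.
        from suitescore.agreement import build_contingency, cohens_kappa
        from suitescore.questionnaire import map_open_ended

        kappas = []
        for seed in range(30):
            cohort, truth = generate_cohort(seed=seed)
            expected = [
                map_open_ended(d.questionnaire.open_ended) for d in cohort.dyads
            ]
            latent = [truth[d.dyad_id] for d in cohort.dyads]
            kappas.append(cohens_kappa(build_contingency(expected, latent)).kappa)
        assert abs(np.mean(kappas) - 0.29) <= 0.1

    def test_cortisol_delta_centred(self):
        deltas = []
        for seed in range(5):
            cohort, _ = generate_cohort(seed=seed)
            deltas += [d.cortisol.delta for d in cohort.dyads if d.cortisol.complete]
        assert abs(np.median(deltas)) < 0.3

    def test_rater_matrix_shape(self, default_cohort):
        cohort, _ = default_cohort
        m = rater_score_matrix(cohort, "valence")
        assert m.shape[1] == 2
        assert m.shape[0] <= 38 * 24


class TestDeterminismAndRoundTrip:
    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        config = GeneratorConfig(n_dyads=12)
        for run in ("one", "two"):
            cohort, truth = generate_cohort(config, seed=77)
            cohort_to_files(cohort, truth, tmp_path / run, config=config)
        for name in ("scores.csv", "questionnaire.csv", "cortisol.csv", "truth.json"):
            assert (tmp_path / "one" / name).read_bytes() == (
                tmp_path / "two" / name
            ).read_bytes()

    def test_files_round_trip_through_readers(self, tmp_path):
        from suitescore import fileio

        config = GeneratorConfig(n_dyads=8)
        cohort, truth = generate_cohort(config, seed=3)
        paths = cohort_to_files(cohort, truth, tmp_path, config=config)

        sheets = fileio.read_scores(paths["scores"])
        original = [s for d in cohort.dyads for s in d.rater_sheets]
        assert len(sheets) == len(original)
        by_key = {(s.dyad_id, s.rater_id): s for s in sheets}
        for s in original:
            assert by_key[(s.dyad_id, s.rater_id)].scores == s.scores

        questionnaires = fileio.read_questionnaires(paths["questionnaire"])
        assert [q.dyad_id for q in questionnaires] == [d.dyad_id for d in cohort.dyads]
        for q, d in zip(questionnaires, cohort.dyads):
            assert q.open_ended == d.questionnaire.open_ended
            for section, items in d.questionnaire.items.items():
                assert q.items[section] == pytest.approx(items)

        pairs = fileio.read_cortisol(paths["cortisol"])
        for p, d in zip(pairs, cohort.dyads):
            if d.cortisol.complete:
                # text round-trip at CSV float precision
                assert p.t0 == pytest.approx(d.cortisol.t0, rel=1e-12)
                assert p.t1 == pytest.approx(d.cortisol.t1, rel=1e-12)

        assert fileio.read_truth(paths["truth"]) == truth

    def test_truth_counts_sum_to_n(self, tmp_path):
        config = GeneratorConfig(n_dyads=15)
        cohort, truth = generate_cohort(config, seed=9)
        paths = cohort_to_files(cohort, truth, tmp_path, config=config)
        doc = json.loads((tmp_path / "truth.json").read_text())
        assert len(doc["latent_classes"]) == 15
        assert doc["generator_config"]["n_dyads"] == 15
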