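"""Synthetic study generator: determinism, calibration, chain fidelity."""

import math

import numpy as np
import pandas as pd
import pytest

from asrt.gmatch import gmatch, score_dataset
from asrt.synthetic import (
    SimulationConfig,
    assign_latent_recall,
    generate_cohort,
    generate_story_bank,
    render_asr_pairs,
    render_retellings,
    simulate_study,
    write_study,
)
from asrt.transcript_prep import cohort_wer


class TestStoryBank:
    def test_default_bank_shape(self):
        bank = generate_story_bank(SimulationConfig(), seed=1)
        short = [s for s in bank.values() if s.length_class == "short"]
        long_ = [s for s in bank.values() if s.length_class == "long"]
        assert len(short) == 18 and len(long_) == 18

    def test_same_seed_identical_banks(self):
        b1 = generate_story_bank(SimulationConfig(), seed=9)
        b2 = generate_story_bank(SimulationConfig(), seed=9)
        assert {k: v.text for k, v in b1.items()} == \
            {k: v.text for k, v in b2.items()}

    def test_word_count_distribution(self):
        cfg = SimulationConfig(n_short=150, n_long=1)
        bank = generate_story_bank(cfg, seed=2)
        counts = [s.word_count for s in bank.values()
                  if s.length_class == "short"]
        # truncated-normal mean ~119 with SD 4.83; MC error ~ 4.83/sqrt(150)
        assert np.mean(counts) == pytest.approx(119, abs=3 * 4.83 / math.sqrt(150))

    def test_sentence_vocabularies_disjoint(self):
        bank = generate_story_bank(SimulationConfig(n_short=2, n_long=2), 3)
        seen: set[str] = set()
        for story in bank.values():
            toks = story.text.lower().replace(".", "").split()
            assert seen.isdisjoint(toks)
            seen.update(toks)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(token_dropout=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(n_cu=0)


class TestCohort:
    def test_cohort_size(self):
        parts, adh, state, truth = generate_cohort(
            SimulationConfig(n_cu=78, n_mci=73), seed=4)
        assert len(parts) == 151
        assert sum(p.group == "CU" for p in parts) == 78

    def test_seed_determinism_byte_identical(self, tmp_path):
        s1 = simulate_study(SimulationConfig(n_cu=5, n_mci=5), seed=21)
        s2 = simulate_study(SimulationConfig(n_cu=5, n_mci=5), seed=21)
        write_study(s1, tmp_path / "a")
        write_study(s2, tmp_path / "b")
        for name in ("participants.csv", "transcripts.csv", "state.csv",
                     "truth/retellings.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_adherence_matches_logistic_closed_form(self):
        # group log-odds -0.97 only, intercept 0.8, no heterogeneity:
        # CU daily adherence = logistic(0.8), MCI = logistic(-0.17)
        cfg = SimulationConfig(
            n_cu=700, n_mci=700,
            adherence_intercept=0.8, adherence_group_immediate=-0.97,
            adherence_group_delayed=-0.97, adherence_day=0.0,
            adherence_age=0.0, adherence_schedule_delayed=0.0,
            adherence_random_sd=0.0)
        _, adh, _, _ = generate_cohort(cfg, seed=6)
        imm = adh[adh["recall_type"] == "immediate"]
        cu = imm[imm["participant_id"].str.slice(1).astype(int) <= 700]
        mci = imm[imm["participant_id"].str.slice(1).astype(int) > 700]
        expit = lambda x: 1 / (1 + np.exp(-x))
        for frame, eta in ((cu, 0.8), (mci, -0.17)):
            n = len(frame)
            mc_err = 3 * math.sqrt(expit(eta) * (1 - expit(eta)) / n)
            assert frame["adherent"].mean() == pytest.approx(expit(eta),
                                                             abs=mc_err)

    def test_state_items_in_range(self, small_study):
        sf = small_study.manifest.state_frame()
        for item in ("mood", "sleep", "mind_wandering", "effort"):
            assert sf[item].between(1, 7).all()


class TestLatentRecall:
    def test_constant_config_gives_constant_p(self):
        cfg = SimulationConfig(
            n_cu=4, n_mci=4, intercept=0.5, effect_group=0, effect_day=0,
            effect_recall=0, effect_length=0, effect_order=0, effect_mood=0,
            effect_mind_wandering=0, random_intercept_sd=0, random_slope_sd=0,
            residual_sd=0, story_difficulty_sd=0)
        rng = np.random.default_rng(8)
        stories = generate_story_bank(cfg, rng)
        parts, adh, _, ptruth = generate_cohort(cfg, rng)
        truth, clamp = assign_latent_recall(parts, adh, stories, cfg, rng,
                                            ptruth)
        assert (truth["p_intended"] == 0.5).all() and clamp == 0.0

    def test_group_separation_matches_configured_effect(self):
        # tolerance must absorb participant-level sampling noise: the mean
        # of ~300 random intercepts (SD 0.10) per group leaves an SE of
        # ~0.008 on the group difference
        cfg = SimulationConfig(n_cu=300, n_mci=300)
        rng = np.random.default_rng(9)
        stories = generate_story_bank(cfg, rng)
        parts, adh, _, ptruth = generate_cohort(cfg, rng)
        truth, _ = assign_latent_recall(parts, adh, stories, cfg, rng, ptruth)
        grp = {p.participant_id: p.group for p in parts}
        truth["group"] = truth["participant_id"].map(grp)
        diff = (truth.loc[truth["group"] == "CU", "p_intended"].mean()
                - truth.loc[truth["group"] == "MCI_AD", "p_intended"].mean())
        assert diff == pytest.approx(0.11, abs=0.03)

    def test_excessive_clamping_warns(self):
        cfg = SimulationConfig(n_cu=10, n_mci=10, intercept=0.98,
                               residual_sd=0.2)
        rng = np.random.default_rng(10)
        stories = generate_story_bank(cfg, rng)
        parts, adh, _, ptruth = generate_cohort(cfg, rng)
        with pytest.warns(UserWarning, match="clamped"):
            assign_latent_recall(parts, adh, stories, cfg, rng, ptruth)


class TestRenderRetellings:
    def test_full_recall_zero_noise_is_verbatim(self, noiseless_config):
        cfg = noiseless_config
        rng = np.random.default_rng(11)
        stories = generate_story_bank(cfg, rng)
        parts, adh, _, ptruth = generate_cohort(cfg, rng)
        truth, _ = assign_latent_recall(parts, adh, stories, cfg, rng, ptruth)
        truth = truth.head(10).assign(p_intended=1.0)
        records, truth = render_retellings(truth, stories, cfg, rng)
        for rec in records:
            assert rec.text == stories[rec.story_id].text
            assert gmatch(stories[rec.story_id].text, rec.text).gmatch == 1.0

    def test_zero_recall_gives_empty_transcript(self, noiseless_config):
        cfg = noiseless_config
        rng = np.random.default_rng(12)
        stories = generate_story_bank(cfg, rng)
        parts, adh, _, ptruth = generate_cohort(cfg, rng)
        truth, _ = assign_latent_recall(parts, adh, stories, cfg, rng, ptruth)
        truth = truth.head(5).assign(p_intended=0.0)
        records, truth = render_retellings(truth, stories, cfg, rng)
        assert all(r.text == "" for r in records)
        assert all(gmatch(stories[r.story_id].text, r.text).gmatch == 0.0
                   for r in records)

    def test_zero_noise_gmatch_equals_coverage_fraction(self, noiseless_study):
        study = noiseless_study
        scores = score_dataset(study.stories,
                               study.manifest.transcripts_frame())
        keys = ["participant_id", "day", "story_id", "recall_type"]
        merged = scores.merge(study.retelling_truth, on=keys)
        assert len(merged) == len(scores)
        np.testing.assert_allclose(merged["gmatch"],
                                   merged["coverage_fraction"], atol=1e-12)


class TestAsrPairs:
    def test_zero_corruption_zero_wer(self, noiseless_study):
        cfg = SimulationConfig(asr_rate_cu=0.0, asr_rate_mci=0.0)
        pairs = render_asr_pairs(noiseless_study.manifest.transcripts,
                                 noiseless_study.manifest.participants,
                                 cfg, seed=13)
        out = cohort_wer(pairs, noiseless_study.manifest.participants_frame())
        assert out["overall_mean"] == 0.0

    def test_configured_rates_recovered_with_group_ordering(self, small_study):
        pairs = render_asr_pairs(small_study.manifest.transcripts,
                                 small_study.manifest.participants,
                                 small_study.config, seed=14)
        out = cohort_wer(pairs, small_study.manifest.participants_frame())
        # corruption inserts fillers-free random tokens; WER tracks the
        # total corruption rate closely at these text lengths
        assert out["group_means"]["CU"] == pytest.approx(0.09, abs=0.02)
        assert out["group_means"]["MCI_AD"] == pytest.approx(0.13, abs=0.02)
        assert out["group_means"]["MCI_AD"] > out["group_means"]["CU"]
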