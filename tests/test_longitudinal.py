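"""Design frames and mixed-model estimation."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from asrt.corpus_io import Participant, Story
from asrt.longitudinal import (
    ModelSpec,
    SeparationError,
    adherence_model_spec,
    build_design,
    effect_table,
    fit_adherence_model,
    fit_performance_model,
    fit_state_model,
    state_model_spec,
    story_model_spec,
    triplet_model_spec,
)


def _full_cohort(n=10, days=(2, 7)):
    """Fully adherent cohort: n participants x days x 3 stories x 2 recalls."""
    parts = pd.DataFrame({
        "participant_id": [f"p{i:02d}" for i in range(n)],
        "group": ["CU" if i % 2 == 0 else "MCI_AD" for i in range(n)],
        "age": 70.0, "sex": ["female" if i % 3 else "male" for i in range(n)],
        "education": 15.0, "schedule": [1 + i % 2 for i in range(n)],
    })
    rows = []
    for pid in parts["participant_id"]:
        for day in range(days[0], days[1] + 1):
            for recall in ("immediate", "delayed"):
                for order in (1, 2, 3):
                    rows.append((pid, day, f"s{order:02d}" if day % 2 == 0
                                 else f"l{order:02d}", recall, order, 0.5))
    scores = pd.DataFrame(rows, columns=["participant_id", "day", "story_id",
                                         "recall_type", "order", "gmatch"])
    stories = {sid: Story(sid, "short" if sid[0] == "s" else "long",
                          "Tok tok.", 2)
               for sid in scores["story_id"].unique()}
    return parts, scores, stories


class TestModelSpecs:
    def test_day_range_restrictions_enforced(self):
        with pytest.raises(ValueError, match="days 2-7"):
            ModelSpec("gmatch_story", ("group",), day_range=(1, 7))
        with pytest.raises(ValueError, match="days 1-7"):
            ModelSpec("adherence_immediate", ("group",), day_range=(2, 7))

    def test_triplet_spec_excludes_order(self):
        assert "order" not in triplet_model_spec().fixed
        assert "order" in story_model_spec().fixed
        with pytest.raises(ValueError, match="order"):
            ModelSpec("gmatch_triplet", ("group", "order"))


class TestBuildDesign:
    def test_row_counts(self):
        parts, scores, stories = _full_cohort(n=10)
        story_frame = build_design(scores, parts, story_model_spec(), stories)
        assert len(story_frame) == 10 * 6 * 3 * 2
        triplet_frame = build_design(scores, parts, triplet_model_spec(),
                                     stories)
        assert len(triplet_frame) == 10 * 6 * 2
        adh_frame = build_design(scores, parts,
                                 adherence_model_spec("immediate"))
        assert len(adh_frame) == 10 * 7

    def test_no_day_outside_range_enters_any_frame(self):
        parts, scores, stories = _full_cohort(n=4)
        extra = scores.head(6).assign(day=1)
        extra2 = scores.head(6).assign(day=8)
        scores = pd.concat([scores, extra, extra2], ignore_index=True)
        for spec in (story_model_spec(), triplet_model_spec()):
            frame = build_design(scores, parts, spec, stories)
            assert frame["day"].between(2, 7).all()
        adh = build_design(scores, parts, adherence_model_spec("immediate"))
        assert adh["day"].between(1, 7).all()

    def test_reference_categories_coded_zero(self):
        parts, scores, stories = _full_cohort(n=4)
        frame = build_design(scores, parts, story_model_spec(), stories)
        cu = parts.loc[parts["group"] == "CU", "participant_id"]
        assert (frame.loc[frame["participant_id"].isin(cu), "group"] == 0).all()
        # immediate recall is the reference level; half the rows are delayed
        assert frame.loc[frame["recall_type"] == 0].shape[0] == \
            frame.loc[frame["recall_type"] == 1].shape[0]

    def test_empty_frame_after_restriction_rejected(self):
        parts, scores, stories = _full_cohort(n=4)
        with pytest.raises(ValueError, match="empty model frame"):
            build_design(scores.assign(day=1), parts, story_model_spec(),
                         stories)


class TestPerformanceModel:
    TRUTH = {"Intercept": 0.5, "group": -0.11, "day": 0.005,
             "recall_type": -0.02, "length": -0.04, "order": 0.02}

    def test_zero_noise_exact_identifiability(self):
        parts, scores, stories = _full_cohort(n=8)
        rng = np.random.default_rng(0)
        frame = build_design(scores, parts, story_model_spec(demographics=False),
                             stories)
        frame["response"] = self.TRUTH["Intercept"] + sum(
            self.TRUTH[k] * frame[k]
            for k in ("group", "day", "recall_type", "length", "order"))
        fit = fit_performance_model(frame,
                                    story_model_spec(demographics=False))
        got = fit.coefficients.set_index("effect")["estimate"]
        for name, val in self.TRUTH.items():
            assert got[name] == pytest.approx(val, abs=1e-5)

    def test_zero_variance_limit_matches_ols(self):
        import statsmodels.api as sm

        parts, scores, stories = _full_cohort(n=8)
        rng = np.random.default_rng(1)
        spec = story_model_spec(demographics=False)
        frame = build_design(scores, parts, spec, stories)
        # residual noise but no participant-level structure at all
        frame["response"] = (0.5 - 0.11 * frame["group"]
                             + rng.normal(0, 0.05, len(frame)))
        fit = fit_performance_model(frame, spec)
        X = sm.add_constant(frame[list(spec.fixed)].to_numpy())
        ols = sm.OLS(frame["response"], X).fit()
        got = fit.coefficients["estimate"].to_numpy()
        np.testing.assert_allclose(got, ols.params, atol=5e-3)

    def test_fallback_is_reported_not_silent(self):
        parts, scores, stories = _full_cohort(n=4)
        rng = np.random.default_rng(2)
        spec = story_model_spec(demographics=False)
        frame = build_design(scores, parts, spec, stories)
        frame["response"] = 0.5 + rng.normal(0, 0.01, len(frame))
        fit = fit_performance_model(frame, spec)
        if fit.method == "reml_intercept_only":
            assert any("falling back" in w for w in fit.warnings)


class TestAdherenceModel:
    @staticmethod
    def _frame(n=60, truth=(0.8, -1.0, -0.05), sigma=1.0, seed=7):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            u = rng.normal(0, sigma)
            g = int(i < n // 2)
            for d in range(1, 8):
                eta = truth[0] + truth[1] * g + truth[2] * d + u
                rows.append((f"p{i:02d}", g, d,
                             int(rng.random() < 1 / (1 + np.exp(-eta)))))
        return pd.DataFrame(rows, columns=["participant_id", "group", "day",
                                           "response"])

    SPEC = ModelSpec("adherence_immediate", ("group", "day"), "intercept",
                     (1, 7))

    def test_matches_lme4_glmer_oracle(self, tmp_path):
        """Independent cross-check against lme4's adaptive quadrature."""
        frame = self._frame()
        fit = fit_adherence_model(frame, self.SPEC)
        csv = tmp_path / "adh.csv"
        frame.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(response ~ group + day + (1 | participant_id),
                       data = d, family = binomial, nAGQ = 25)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), sep = "\\n")
        """)
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, check=True)
        ref = [float(x) for x in out.stdout.strip().splitlines()]
        got = fit.coefficients["estimate"].tolist()
        np.testing.assert_allclose(got, ref[:3], atol=2e-3)
        sigma = fit.random_variances["participant_intercept_var"] ** 0.5
        assert sigma == pytest.approx(ref[3], abs=5e-3)

    def test_all_adherent_raises_separation(self):
        frame = self._frame()
        frame["response"] = 1
        with pytest.raises(SeparationError, match="constant"):
            fit_adherence_model(frame, self.SPEC)

    def test_zero_variance_limit_matches_plain_logistic(self):
        import statsmodels.api as sm

        frame = self._frame(n=80, sigma=0.0, seed=12)
        fit = fit_adherence_model(frame, self.SPEC)
        X = sm.add_constant(frame[["group", "day"]].to_numpy(dtype=float))
        glm = sm.GLM(frame["response"].to_numpy(dtype=float), X,
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coefficients["estimate"].to_numpy(),
                                   glm.params, atol=0.02)


class TestStateModel:
    @staticmethod
    def _frames(seed=3, state_sd=1.5):
        rng = np.random.default_rng(seed)
        parts, scores, stories = _full_cohort(n=12)
        state_rows = []
        for pid in parts["participant_id"]:
            for day in range(2, 8):
                mood = int(np.clip(round(4 + state_sd * rng.normal()), 1, 7)) \
                    if state_sd else 4
                mw = int(np.clip(round(4 + state_sd * rng.normal()), 1, 7)) \
                    if state_sd else 4
                state_rows.append((pid, day, mood, 4, mw, 4))
        state = pd.DataFrame(state_rows, columns=[
            "participant_id", "day", "mood", "sleep", "mind_wandering",
            "effort"])
        merged = scores.merge(state, on=["participant_id", "day"])
        merged["gmatch"] = (0.5 + 0.007 * (merged["mood"] - 4)
                            - 0.007 * (merged["mind_wandering"] - 4)
                            + rng.normal(0, 0.03, len(merged)))
        merged["gmatch"] = merged["gmatch"].clip(0, 1)
        return parts, merged[scores.columns], stories, state

    def test_recovers_state_effect_signs(self):
        hits = 0
        for rep in range(8):
            parts, scores, stories, state = self._frames(seed=100 + rep)
            frame = build_design(scores, parts,
                                 state_model_spec(demographics=False),
                                 stories, state_reports=state)
            fit = fit_state_model(frame, state_model_spec(demographics=False))
            est = fit.coefficients.set_index("effect")["estimate"]
            hits += (est["mood"] > 0) and (est["mind_wandering"] < 0)
        assert hits >= 7

    def test_constant_state_items_dropped_to_base_model(self):
        parts, scores, stories, state = self._frames(state_sd=0.0)
        spec = state_model_spec(demographics=False)
        frame = build_design(scores, parts, spec, stories, state_reports=state)
        fit = fit_state_model(frame, spec)
        assert sum("no variance" in w for w in fit.warnings) == 4
        base_spec = triplet_model_spec(demographics=False)
        base = fit_performance_model(
            build_design(scores, parts, base_spec, stories), base_spec)
        merged = fit.coefficients.merge(base.coefficients, on="effect",
                                        suffixes=("_state", "_base"))
        np.testing.assert_allclose(merged["estimate_state"],
                                   merged["estimate_base"], atol=1e-6)

    def test_all_missing_state_column_rejected(self):
        parts, scores, stories, state = self._frames()
        spec = state_model_spec(demographics=False)
        frame = build_design(scores, parts, spec, stories, state_reports=state)
        frame["effort"] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            fit_state_model(frame, spec)


class TestEffectTable:
    def test_d_column_follows_2t_over_sqrt_df(self):
        parts, scores, stories = _full_cohort(n=8)
        rng = np.random.default_rng(4)
        spec = story_model_spec(demographics=False)
        frame = build_design(scores, parts, spec, stories)
        frame["response"] = (0.5 - 0.1 * frame["group"]
                             + rng.normal(0, 0.05, len(frame)))
        fit = fit_performance_model(frame, spec)
        table = effect_table(fit)
        assert len(table) == len(spec.fixed) + 1  # + intercept
        np.testing.assert_allclose(
            table["d"], 2 * table["stat"] / np.sqrt(fit.residual_df))

    def test_zero_t_gives_zero_d(self):
        import pandas as pd

        from asrt.longitudinal import ModelFit

        coefs = pd.DataFrame({"effect": ["x"], "estimate": [0.0], "se": [1.0],
                              "stat": [0.0], "p": [1.0], "ci_low": [-2.0],
                              "ci_high": [2.0]})
        fit = ModelFit(coefs, {}, 100.0, 110, True, "reml", "gaussian")
        assert effect_table(fit)["d"].iloc[0] == 0.0

    def test_nonconverged_fit_rejected(self):
        import pandas as pd

        from asrt.longitudinal import ModelFit

        coefs = pd.DataFrame({"effect": ["x"], "estimate": [0.0], "se": [1.0],
                              "stat": [0.0], "p": [1.0], "ci_low": [0.0],
                              "ci_high": [0.0]})
        fit = ModelFit(coefs, {}, 100.0, 110, False, "reml", "gaussian")
        with pytest.raises(ValueError, match="non-converged"):
            effect_table(fit)
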