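"""Longitudinal mixed-effects models for task performance and adherence.

Performance (G-match per story or per triplet) is modeled with a linear
mixed model: fixed effects of group, assessment day, recall type, story
length, presentation order (story-level only) and demographics, with a
participant random intercept and random day slope (unstructured 2x2
covariance), fitted by REML. Performance analyses are restricted to remote
days 2-7, when stimuli are novel and common to both schedules.

Adherence (did the participant engage with at least one story that day) is
modeled with a mixed logistic regression, random intercept per
participant, over days 1-7. The marginal likelihood is maximized directly
via Gauss-Hermite quadrature over the random intercept, i.e. the same
estimand as lme4::glmer; standard errors come from the numerical Hessian
at the optimum.

Daily self-reported state (mood, sleep, effort, mind-wandering) enters the
triplet performance model as four additional fixed covariates.

Per-effect Cohen d for performance models uses the multilevel convention
d = 2t/sqrt(residual df) with residual df = nobs - n_fixed_effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "ModelFit",
    "SeparationError",
    "story_model_spec",
    "triplet_model_spec",
    "adherence_model_spec",
    "state_model_spec",
    "build_design",
    "fit_performance_model",
    "fit_adherence_model",
    "fit_state_model",
    "effect_table",
]


class SeparationError(RuntimeError):
    """Raised when a binary response is perfectly separated (or constant)."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one of the study's models.

    ``response`` is one of gmatch_story, gmatch_triplet,
    adherence_immediate, adherence_delayed. ``fixed`` lists design-frame
    columns in reporting order. Reference categories (coded 0): CU,
    immediate recall, short stories, female.
    """

    response: str
    fixed: tuple[str, ...]
    random: str = "intercept_and_slope"
    day_range: tuple[int, int] = (2, 7)

    def __post_init__(self):
        if self.response.startswith("gmatch") and self.day_range != (2, 7):
            raise ValueError("performance models are restricted to days 2-7")
        if self.response.startswith("adherence") and self.day_range != (1, 7):
            raise ValueError("adherence models are restricted to days 1-7")
        if self.response == "gmatch_triplet" and "order" in self.fixed:
            raise ValueError("the triplet model does not include an order effect")


DEMOGRAPHICS = ("sex", "education", "age")


def story_model_spec(demographics: bool = True) -> ModelSpec:
    fixed = ("group", "day", "recall_type", "length", "order")
    if demographics:
        fixed += DEMOGRAPHICS
    return ModelSpec("gmatch_story", fixed, "intercept_and_slope", (2, 7))


def triplet_model_spec(demographics: bool = True) -> ModelSpec:
    fixed = ("group", "day", "recall_type", "length")
    if demographics:
        fixed += DEMOGRAPHICS
    return ModelSpec("gmatch_triplet", fixed, "intercept_and_slope", (2, 7))


def adherence_model_spec(recall_type: str = "immediate",
                         demographics: bool = True) -> ModelSpec:
    fixed: tuple[str, ...] = ("group", "day", "schedule")
    if demographics:
        fixed += DEMOGRAPHICS
    return ModelSpec(f"adherence_{recall_type}", fixed, "intercept", (1, 7))


STATE_ITEMS = ("mood", "sleep", "effort", "mind_wandering")


def state_model_spec(demographics: bool = True) -> ModelSpec:
    base = triplet_model_spec(demographics)
    return ModelSpec("gmatch_triplet", base.fixed + STATE_ITEMS,
                     base.random, base.day_range)


@dataclass
class ModelFit:
    """Fitted-model surface: one coefficient row per fixed effect."""

    coefficients: pd.DataFrame  # effect, estimate, se, stat, p, ci_low, ci_high
    random_variances: dict
    residual_df: float
    nobs: int
    converged: bool
    method: str
    kind: str  # gaussian | binomial
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# design frames

_BINARY_CODES = {
    "group": ({"CU": 0, "MCI_AD": 1}, "group"),
    "recall_type": ({"immediate": 0, "delayed": 1}, "recall_type"),
    "length": ({"short": 0, "long": 1}, "length_class"),
    "sex": ({"female": 0, "male": 1}, "sex"),
    "schedule": ({1: 0, 2: 1}, "schedule"),
}


def build_design(
    scores: pd.DataFrame,
    participants: pd.DataFrame,
    spec: ModelSpec,
    stories: Mapping | None = None,
    state_reports: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the model frame for ``spec``.

    Story-level frames have one row per retelling, triplet frames one row
    per (participant, day, recall type) session, adherence frames one row
    per participant-day-recall-type cell over days 1-7 (absent rows in
    ``scores``/transcripts meaning non-engagement, coded 0). Rows with
    missing covariates are dropped (complete-case).
    """
    parts = participants.copy()
    if spec.response.startswith("adherence"):
        recall = spec.response.split("_", 1)[1]
        sub = scores[(scores["recall_type"] == recall)
                     & scores["day"].between(*spec.day_range)]
        present = set(zip(sub["participant_id"], sub["day"]))
        rows = [
            {"participant_id": pid, "day": day,
             "adherent": int((pid, day) in present)}
            for pid in parts["participant_id"]
            for day in range(spec.day_range[0], spec.day_range[1] + 1)
        ]
        frame = pd.DataFrame(rows).merge(parts, on="participant_id")
        frame["response"] = frame["adherent"]
    else:
        df = scores[scores["day"].between(*spec.day_range)].copy()
        df = df[df["gmatch"].notna()]
        if "length_class" not in df.columns:
            if stories is None:
                raise ValueError("need story bank or length_class column "
                                 "to code story length")
            df["length_class"] = df["story_id"].map(
                lambda s: stories[s].length_class)
        if spec.response == "gmatch_triplet":
            df = (df.groupby(["participant_id", "day", "recall_type"],
                             as_index=False)
                  .agg(gmatch=("gmatch", "mean"),
                       length_class=("length_class",
                                     lambda s: s.mode().iat[0])))
        frame = df.merge(parts, on="participant_id")
        frame["response"] = frame["gmatch"]
        if state_reports is not None:
            frame = frame.merge(state_reports, on=["participant_id", "day"],
                                how="left")
    for effect in spec.fixed:
        if effect in _BINARY_CODES:
            mapping, col = _BINARY_CODES[effect]
            frame[effect] = frame[col].map(mapping)
        elif effect not in frame.columns:
            raise ValueError(f"design frame lacks covariate {effect!r}")
    cols = list(dict.fromkeys(["participant_id", "day", "response"]
                              + list(spec.fixed)))
    frame = frame.loc[:, cols].dropna()
    if len(frame) == 0:
        raise ValueError("empty model frame after day-range restriction "
                         "and complete-case filtering")
    return frame.reset_index(drop=True)


# ---------------------------------------------------------------------------
# linear mixed models (statsmodels MixedLM, REML)


def _coef_frame(names, est, se, dist: str, df: float | None = None) -> pd.DataFrame:
    est = np.asarray(est, dtype=float)
    se = np.asarray(se, dtype=float)
    stat = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    if dist == "t" and df is not None and df > 0:
        p = 2 * stats.t.sf(np.abs(stat), df)
        crit = stats.t.ppf(0.975, df)
    else:
        p = 2 * stats.norm.sf(np.abs(stat))
        crit = stats.norm.ppf(0.975)
    return pd.DataFrame({
        "effect": names, "estimate": est, "se": se, "stat": stat, "p": p,
        "ci_low": est - crit * se, "ci_high": est + crit * se,
    })


def fit_performance_model(frame: pd.DataFrame, spec: ModelSpec,
                          maxiter: int = 200) -> ModelFit:
    """REML linear mixed model for a performance frame.

    Random structure per ``spec``: participant intercept plus day slope
    with unstructured covariance; if that fit fails or lands on a singular
    covariance, the model falls back to a random intercept only and says
    so in ``ModelFit.warnings`` — never silently.
    """
    import statsmodels.formula.api as smf

    formula = "response ~ " + " + ".join(spec.fixed)
    notes: list[str] = []

    def _try(re_formula):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = smf.mixedlm(formula, frame, groups=frame["participant_id"],
                                re_formula=re_formula)
            res = model.fit(reml=True, maxiter=maxiter)
        msgs = [str(c.message) for c in caught]
        return res, msgs

    method = "reml_intercept_slope"
    res = None
    if spec.random == "intercept_and_slope":
        try:
            res, msgs = _try("~day")
            cov_re = res.cov_re.to_numpy()
            if (not res.converged or np.any(np.diag(cov_re) <= 0)
                    or np.linalg.det(cov_re) <= 0):
                notes.append("random-slope covariance singular or "
                             "non-converged; falling back to random intercept")
                res = None
        except (np.linalg.LinAlgError, ValueError) as exc:
            notes.append(f"random-slope fit failed ({exc}); "
                         "falling back to random intercept")
            res = None
    if res is None:
        res, msgs = _try("~1")
        method = "reml_intercept_only"
    notes.extend(m for m in msgs if "ConvergenceWarning" in m or "boundary" in m)
    if not res.converged:
        notes.append("REML estimation did not converge")
    names = list(res.fe_params.index)
    k = len(names)
    residual_df = float(res.nobs - k)
    coefs = _coef_frame(names, res.fe_params.to_numpy(),
                        res.bse_fe.to_numpy(), "t", residual_df)
    rv = {f"re_{r}_{c}": float(res.cov_re.loc[r, c])
          for r in res.cov_re.index for c in res.cov_re.columns}
    rv["residual_var"] = float(res.scale)
    return ModelFit(coefs, rv, residual_df, int(res.nobs),
                    bool(res.converged), method, "gaussian", notes)


def fit_state_model(frame: pd.DataFrame, spec: ModelSpec | None = None) -> ModelFit:
    """Triplet performance model augmented with daily state covariates.

    Zero-variance state columns are dropped with a warning (a constant
    covariate is unidentifiable against the intercept); an all-missing
    state column is an error. The frame must come from ``build_design``
    with ``state_reports`` supplied.
    """
    spec = spec or state_model_spec()
    keep = []
    notes = []
    for item in spec.fixed:
        if item in STATE_ITEMS:
            col = frame[item]
            if col.isna().all():
                raise ValueError(f"state covariate {item!r} is entirely missing")
            if col.nunique(dropna=True) < 2:
                notes.append(f"state covariate {item!r} has no variance; dropped")
                continue
        keep.append(item)
    reduced = ModelSpec(spec.response, tuple(keep), spec.random, spec.day_range)
    fit = fit_performance_model(frame, reduced)
    fit.warnings = notes + fit.warnings
    return fit


# ---------------------------------------------------------------------------
# mixed logistic adherence model (Gauss-Hermite marginal MLE)


def _gh_nll(params: np.ndarray, y: np.ndarray, X: np.ndarray,
            group_idx: np.ndarray, n_groups: int,
            nodes: np.ndarray, log_wts: np.ndarray) -> float:
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    eta0 = X @ beta
    per_group = np.empty((n_groups, len(nodes)))
    for k, (x_k, lw_k) in enumerate(zip(nodes, log_wts)):
        eta = eta0 + np.sqrt(2.0) * sigma * x_k
        ll_obs = y * eta - np.logaddexp(0.0, eta)
        per_group[:, k] = np.bincount(group_idx, weights=ll_obs,
                                      minlength=n_groups) + lw_k
    return -float(special.logsumexp(per_group, axis=1).sum())


def fit_adherence_model(frame: pd.DataFrame, spec: ModelSpec,
                        n_nodes: int = 31) -> ModelFit:
    """Random-intercept logistic model for daily adherence.

    Maximizes the marginal likelihood, integrating the participant random
    intercept by Gauss-Hermite quadrature (``n_nodes`` nodes), and reports
    log-odds estimates with Wald (normal) inference from the numerical
    Hessian. Constant responses and perfect separation are reported as
    ``SeparationError`` rather than returning runaway estimates.
    """
    import statsmodels.api as sm
    from statsmodels.tools import numdiff

    y = frame["response"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise SeparationError(
            "adherence response is constant (all "
            f"{int(y[0])}); the model is not identifiable")
    X = np.column_stack([np.ones(len(frame))]
                        + [frame[c].to_numpy(dtype=float) for c in spec.fixed])
    names = ["Intercept"] + list(spec.fixed)
    groups, group_idx = np.unique(frame["participant_id"], return_inverse=True)

    # start from the marginal (no random effect) logistic fit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start_beta = sm.GLM(y, X, family=sm.families.Binomial()).fit().params
    nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)
    log_wts = np.log(wts) - 0.5 * np.log(np.pi)
    x0 = np.append(start_beta, 0.0)
    args = (y, X, group_idx, len(groups), nodes, log_wts)
    res = optimize.minimize(_gh_nll, x0, args=args, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-6})
    notes = []
    if not res.success:
        # BFGS with numeric gradients can stall on precision loss near the
        # optimum; polish with Nelder-Mead before giving up
        res2 = optimize.minimize(_gh_nll, res.x, args=args, method="Nelder-Mead",
                                 options={"maxiter": 2000, "xatol": 1e-8,
                                          "fatol": 1e-10})
        if res2.fun <= res.fun:
            res = res2
        if not res.success:
            notes.append(f"optimizer reported: {res.message}")
    params = res.x
    if np.any(np.abs(params[:-1]) > 15):
        raise SeparationError(
            "runaway log-odds estimate suggests complete separation: "
            + ", ".join(f"{n}={v:.1f}" for n, v in zip(names, params[:-1])
                        if abs(v) > 15))
    hess = numdiff.approx_hess(params, _gh_nll, args=args)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(len(params), np.nan)
        notes.append("Hessian not invertible; standard errors unavailable")
    coefs = _coef_frame(names, params[:-1], se_all[:-1], "z")
    sigma = float(np.exp(params[-1]))
    converged = bool(res.success) or not notes
    return ModelFit(coefs, {"participant_intercept_var": sigma ** 2},
                    float(len(frame) - X.shape[1]), len(frame),
                    converged, f"gauss_hermite_{n_nodes}", "binomial", notes)


# ---------------------------------------------------------------------------
# effect tables


def effect_table(fit: ModelFit) -> pd.DataFrame:
    """Per-effect report rows; Cohen d (2t/sqrt(df)) for performance models."""
    from .psychometrics import d_to_auc, t_to_d

    if not fit.converged:
        raise ValueError("refusing to tabulate a non-converged fit")
    if fit.residual_df is None or not np.isfinite(fit.residual_df):
        raise ValueError("missing residual df")
    out = fit.coefficients.loc[:, ["effect", "estimate", "se", "stat", "p"]].copy()
    if fit.kind == "gaussian":
        out["d"] = [t_to_d(t, fit.residual_df) for t in out["stat"]]
        out["auc_equivalent"] = [d_to_auc(d) for d in out["d"]]
    return out
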