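"""Reliability, validity, contingency and effect-size analytics.

Parallel-forms reliability of the story stimuli is summarized by pairwise
Spearman correlations between per-story (or per-triplet) scores across
participants, with pairwise-complete deletion — adherence is optional, so
different story pairs are observed in different subsets of participants.
Convergent validity correlates task scores with external cognitive and
clinical measures. Group composition tables are tested with Pearson
chi-square (no continuity correction), group means with Welch's t.

Effect sizes for mixed-model fixed effects use the multilevel convention
d = 2t/sqrt(df); the AUC equivalent of a Cohen d under the binormal
equal-variance model is Phi(d/sqrt(2)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReliabilityMatrix",
    "spearman_matrix",
    "convergent_validity",
    "pearson_chi_square",
    "welch_t",
    "WelchResult",
    "t_to_d",
    "d_to_auc",
    "adherence_summary",
    "benjamini_hochberg",
]


@dataclass
class ReliabilityMatrix:
    """Pairwise-complete Spearman correlation matrix with pair counts."""

    rho: pd.DataFrame
    n_pairs: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.rho.columns)

    def offdiagonal(self) -> np.ndarray:
        vals = self.rho.to_numpy(dtype=float)
        iu = np.triu_indices_from(vals, k=1)
        off = vals[iu]
        return off[~np.isnan(off)]

    def summary(self) -> dict:
        off = self.offdiagonal()
        if off.size == 0:
            return {"mean": float("nan"), "min": float("nan"),
                    "max": float("nan"), "n": 0}
        return {"mean": float(off.mean()), "min": float(off.min()),
                "max": float(off.max()), "n": int(off.size)}


def spearman_matrix(table: pd.DataFrame, min_pairs: int = 3) -> ReliabilityMatrix:
    """Spearman rho between every pair of columns, pairwise-complete.

    ``table`` is wide: one row per participant, one column per story or
    triplet. A pair with fewer than ``min_pairs`` complete observations, or
    with a constant column on its complete cases, gets a missing rho (the
    latter with a warning). Ties are average-ranked.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    cols = list(table.columns)
    notna = table.notna().to_numpy()
    n_pairs = pd.DataFrame(notna.T.astype(int) @ notna.astype(int),
                           index=cols, columns=cols)
    rho = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    for i, a in enumerate(cols):
        rho.loc[a, a] = 1.0
        for b in cols[i + 1:]:
            mask = table[a].notna() & table[b].notna()
            if mask.sum() < min_pairs:
                continue
            x, y = table.loc[mask, a], table.loc[mask, b]
            if x.nunique() < 2 or y.nunique() < 2:
                warnings.warn(f"constant column in pair ({a}, {b}); "
                              "rho undefined", stacklevel=2)
                continue
            r = stats.spearmanr(x, y).statistic
            rho.loc[a, b] = rho.loc[b, a] = float(r)
    return ReliabilityMatrix(rho, n_pairs)


def convergent_validity(
    scores: pd.DataFrame,
    external: pd.DataFrame,
    flip_sign: tuple[str, ...] = (),
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Spearman rho between each task measure and each external measure.

    ``scores`` and ``external`` are wide tables indexed by participant.
    Columns named in ``flip_sign`` (e.g. a dementia-severity scale where
    higher is worse) have their correlation signs reversed for display
    consistency. Returns a long table (measure, external, rho, n).
    """
    joined = scores.join(external, how="inner")
    rows = []
    for m in scores.columns:
        for e in external.columns:
            mask = joined[m].notna() & joined[e].notna()
            n = int(mask.sum())
            if n < min_pairs:
                raise ValueError(
                    f"fewer than {min_pairs} complete pairs for ({m}, {e})")
            r = float(stats.spearmanr(joined.loc[mask, m],
                                      joined.loc[mask, e]).statistic)
            if e in flip_sign:
                r = -r
            rows.append((m, e, r, n))
    return pd.DataFrame(rows, columns=["measure", "external", "rho", "n"])


def pearson_chi_square(a: int, b: int, c: int, d: int) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]].

    No continuity correction: X2 = N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),
    1 df. Degenerate margins (an all-zero row or column) are an error.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("negative cell count")
    n = cells.sum()
    margins = [a + b, c + d, a + c, b + d]
    if n < 1 or any(m == 0 for m in margins):
        raise ValueError("degenerate margin in 2x2 table")
    stat = n * (a * d - b * c) ** 2 / np.prod(margins, dtype=float)
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), 1, p


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    d: float


def welch_t(group_a, group_b) -> WelchResult:
    """Welch two-sample t (Satterthwaite df) with pooled-SD Cohen d.

    d uses the pooled standard deviation (not Welch's), the usual
    convention when reporting alongside an unequal-variance test. Sign
    convention: positive t/d means group A > group B.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0, 0.0)
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
                 / (na + nb - 2))
    d = float((np.mean(a) - np.mean(b)) / sp) if sp > 0 else 0.0
    return WelchResult(float(res.statistic), float(res.df),
                       float(res.pvalue), d)


def t_to_d(t: float, residual_df: float) -> float:
    """Cohen d from a mixed-model t statistic: d = 2t/sqrt(df)."""
    if residual_df <= 0:
        raise ValueError("residual df must be positive")
    return 2.0 * t / np.sqrt(residual_df)


def d_to_auc(d: float) -> float:
    """AUC equivalent of a Cohen d: Phi(d/sqrt(2)).

    This is the probability that a random case scores above a random
    control under equal-variance normal score distributions separated by
    d pooled SDs; d=0 gives chance (0.5).
    """
    return float(stats.norm.cdf(d / np.sqrt(2.0)))


def adherence_summary(
    transcripts: pd.DataFrame,
    participants: pd.DataFrame,
    day_range: tuple[int, int] = (1, 7),
    ndigits: int = 1,
) -> dict:
    """Engagement and daily-adherence percentages.

    Engagement = the participant produced at least one remote retelling
    row. Daily adherence (per recall type) = fraction of participant-days
    in ``day_range`` with at least one retelling of that type, averaged
    within group. Percentages are rounded to ``ndigits`` for report
    parity.
    """
    if len(participants) == 0:
        raise ValueError("empty cohort")
    pids = participants["participant_id"]
    engaged_ids = set(transcripts["participant_id"].unique())
    engaged = pids.isin(engaged_ids)
    out = {
        "n_total": int(len(pids)),
        "n_engaged": int(engaged.sum()),
        "engagement_pct": round(100.0 * engaged.mean(), ndigits),
        "by_group": {},
        "daily_adherence_pct": {},
    }
    for grp, sub in participants.groupby("group", sort=True):
        eng = sub["participant_id"].isin(engaged_ids)
        out["by_group"][grp] = {
            "n_total": int(len(sub)),
            "n_engaged": int(eng.sum()),
            "engagement_pct": round(100.0 * eng.mean(), ndigits),
        }
    days = range(day_range[0], day_range[1] + 1)
    engaged_parts = participants[engaged.to_numpy()]
    for recall in ("immediate", "delayed"):
        sub = transcripts[(transcripts["recall_type"] == recall)
                          & transcripts["day"].between(*day_range)]
        present = set(zip(sub["participant_id"], sub["day"]))
        per_group = {}
        for grp, gsub in engaged_parts.groupby("group", sort=True):
            cells = [(pid, day) for pid in gsub["participant_id"] for day in days]
            if cells:
                frac = np.mean([c in present for c in cells])
                per_group[grp] = round(100.0 * float(frac), ndigits)
        out["daily_adherence_pct"][recall] = per_group
    return out


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p-values are reported by default)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
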