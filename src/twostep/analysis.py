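"""Stay-probability statistics for the two-step task.

A trial counts as a "stay" when the first-stage choice repeats the previous
trial's; it is binned by the *previous* trial's reward and transition type.
Model-free control shows up as a main effect of Reward on staying; model-based
control shows up as the Reward × Transition interaction, because only a
forward planner treats a rewarded rare transition as evidence for switching.
The two per-subject contrast scores are

    interaction  = (RC − RR) − (UC − UR)
    reward main  = (RC + RR) − (UC + UR)

with RC/RR/UC/UR the stay probabilities after Rewarded-Common, Rewarded-Rare,
Unrewarded-Common and Unrewarded-Rare trials.

The mixed 2×2×(groups) ANOVA is computed exactly via orthonormal per-subject
contrast scores: with two-level within factors the split-plot decomposition
separates into four independent between-subject models (cell mean, reward,
transition, and interaction scores), each analysed with type III sums of
squares under sum-to-zero group coding.  This reproduces the classical
univariate mixed ANOVA to machine precision, and makes the equivalence
between the three-way interaction F and the one-way F on per-subject
interaction terms explicit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .task import COMMON, SessionData

__all__ = [
    "StayTable",
    "stay_probabilities",
    "contrast_terms",
    "cohort_stay_frame",
    "three_way_anova",
    "pairwise_group_comparisons",
    "eta_squared_h",
    "kruskal_wallis_eta2",
    "BmiRegressionResult",
    "bmi_polynomial_regression",
    "orthogonal_poly",
    "normality_variance_screen",
    "accumulated_reward",
    "accumulated_reward_analysis",
]

logger = logging.getLogger(__name__)

CELLS = ("rc", "rr", "uc", "ur")  # (previous) rewarded/unrewarded × common/rare

ANOVA_EFFECTS = (
    "Group",
    "Reward",
    "Group:Reward",
    "Transition",
    "Group:Transition",
    "Reward:Transition",
    "Group:Reward:Transition",
)


@dataclass(frozen=True)
class StayTable:
    """Per-subject stay probabilities for the 2×2 previous-trial conditions.

    Empty cells are NaN (flagged, never coerced to 0); ``n_*`` count the
    trials contributing to each cell and ``n_dropped`` counts trials without
    a predecessor (the first trial of a session).
    """

    subject_id: str
    p_rc: float
    p_rr: float
    p_uc: float
    p_ur: float
    n_rc: int
    n_rr: int
    n_uc: int
    n_ur: int
    n_dropped: int = 1
    group: str | None = None
    bmi: float | None = None

    @property
    def cells(self) -> np.ndarray:
        return np.array([self.p_rc, self.p_rr, self.p_uc, self.p_ur])

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite(self.cells)))

    @property
    def interaction_term(self) -> float:
        return (self.p_rc - self.p_rr) - (self.p_uc - self.p_ur)

    @property
    def reward_main_term(self) -> float:
        return (self.p_rc + self.p_rr) - (self.p_uc + self.p_ur)


def stay_probabilities(session: SessionData) -> StayTable:
    """Per-cell stay fractions of one session (first trial has no predecessor)."""
    if session.n_trials < 2:
        raise ValueError("stay probabilities require at least 2 trials")
    a1 = session.first_choice
    stay = a1[1:] == a1[:-1]
    prev_rew = session.reward[:-1] == 1
    prev_common = session.transition[:-1] == COMMON
    masks = {
        "rc": prev_rew & prev_common,
        "rr": prev_rew & ~prev_common,
        "uc": ~prev_rew & prev_common,
        "ur": ~prev_rew & ~prev_common,
    }
    p, n = {}, {}
    for cell, mask in masks.items():
        n[cell] = int(mask.sum())
        p[cell] = float(stay[mask].mean()) if n[cell] else float("nan")
    return StayTable(
        subject_id=session.subject_id,
        group=session.group,
        bmi=session.bmi,
        n_dropped=1,
        **{f"p_{c}": p[c] for c in CELLS},
        **{f"n_{c}": n[c] for c in CELLS},
    )


def contrast_terms(table: StayTable) -> tuple[float, float]:
    """(interaction term, reward main-effect term); errors on undefined cells."""
    if not table.complete:
        empty = [c for c in CELLS if not np.isfinite(getattr(table, f"p_{c}"))]
        raise ValueError(
            f"subject {table.subject_id}: empty stay cell(s) {empty}; contrasts undefined"
        )
    return table.interaction_term, table.reward_main_term


def cohort_stay_frame(sessions: list[SessionData]) -> pd.DataFrame:
    """Stay tables and contrast scores for a cohort, one row per subject."""
    rows = []
    for s in sessions:
        t = stay_probabilities(s)
        rows.append(
            {
                "subject_id": t.subject_id,
                "group": t.group,
                "bmi": t.bmi,
                "p_stay_rc": t.p_rc,
                "p_stay_rr": t.p_rr,
                "p_stay_uc": t.p_uc,
                "p_stay_ur": t.p_ur,
                "interaction_term": t.interaction_term,
                "reward_main_term": t.reward_main_term,
                "n_dropped": t.n_dropped,
            }
        )
    return pd.DataFrame(rows)


def _type3_oneway(score: np.ndarray, group: np.ndarray) -> dict[str, dict]:
    """Type III tests of the intercept and of group on one contrast score.

    Under sum-to-zero coding the intercept estimates the unweighted mean of
    the group means, which is the type III test of the within-subject effect
    in the corresponding stratum of the split-plot design.
    """
    df = pd.DataFrame({"score": score, "group": group})
    fit = smf.ols("score ~ C(group, Sum)", data=df).fit()
    an = sm.stats.anova_lm(fit, typ=3)
    resid_ss = float(an.loc["Residual", "sum_sq"])
    df_resid = float(an.loc["Residual", "df"])
    out = {}
    for row, label in (("Intercept", "within"), ("C(group, Sum)", "group")):
        ss = float(an.loc[row, "sum_sq"])
        denom = ss + resid_ss
        out[label] = {
            "F": float(an.loc[row, "F"]),
            "df1": float(an.loc[row, "df"]),
            "df2": df_resid,
            "p": float(an.loc[row, "PR(>F)"]),
            "partial_eta_sq": ss / denom if denom > 0 else 0.0,
        }
    return out


def three_way_anova(stay: pd.DataFrame) -> pd.DataFrame:
    """Mixed Group × Reward × Transition ANOVA (type III) on stay probabilities.

    ``stay`` needs columns ``p_stay_rc/rr/uc/ur`` and ``group``.  Subjects
    with any undefined cell are dropped with a warning.  Returns a frame
    indexed by effect with F, df1, df2, p and partial η².
    """
    cols = [f"p_stay_{c}" for c in CELLS]
    cells = stay[cols].to_numpy(float)
    ok = np.all(np.isfinite(cells), axis=1)
    if not ok.all():
        logger.warning("dropping %d subject(s) with empty stay cells", int((~ok).sum()))
    cells = cells[ok]
    group = stay.loc[ok, "group"].astype(str).to_numpy()
    if len(np.unique(group)) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    rc, rr, uc, ur = cells.T
    # orthonormal within-subject contrasts (coefficients ±1/2)
    scores = {
        "between": (rc + rr + uc + ur) / 2.0,
        "Reward": (rc + rr - uc - ur) / 2.0,
        "Transition": (rc - rr + uc - ur) / 2.0,
        "Reward:Transition": (rc - rr - uc + ur) / 2.0,
    }
    rows: dict[str, dict] = {}
    rows["Group"] = _type3_oneway(scores["between"], group)["group"]
    for name in ("Reward", "Transition", "Reward:Transition"):
        res = _type3_oneway(scores[name], group)
        rows[name] = res["within"]
        rows[f"Group:{name}"] = res["group"]
    return pd.DataFrame(rows).T.loc[list(ANOVA_EFFECTS)]


def pairwise_group_comparisons(
    values: np.ndarray,
    groups: np.ndarray,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Planned pairwise equal-variance t-tests between groups (uncorrected).

    Pairs with fewer than 2 subjects in either group are skipped with a
    warning.  Returns a frame with columns group_a, group_b, t, df, p.
    """
    values = np.asarray(values, float)
    groups = np.asarray([str(g) for g in groups])
    labels = list(dict.fromkeys(groups))
    if pairs is None:
        pairs = list(itertools.combinations(labels, 2))
    rows = []
    for a, b in pairs:
        xa, xb = values[groups == a], values[groups == b]
        if len(xa) < 2 or len(xb) < 2:
            logger.warning("skipping pair (%s, %s): fewer than 2 subjects", a, b)
            continue
        t, p = st.ttest_ind(xa, xb, equal_var=True)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(t),
                "df": len(xa) + len(xb) - 2,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def eta_squared_h(H: float, k: int, n: int) -> float:
    """Rank-based effect size for a Kruskal–Wallis test: (H − k + 1)/(n − k)."""
    return (H - k + 1) / (n - k)


def kruskal_wallis_eta2(
    values: np.ndarray, groups: np.ndarray
) -> tuple[float, float, float]:
    """Kruskal–Wallis H (midrank tie correction), chi-square p, and η²_H."""
    values = np.asarray(values, float)
    groups = np.asarray([str(g) for g in groups])
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 groups")
    samples = [values[groups == g] for g in labels]
    H, p = st.kruskal(*samples)
    return float(H), float(p), eta_squared_h(float(H), len(labels), len(values))


def orthogonal_poly(x: np.ndarray, degree: int = 2) -> np.ndarray:
    """Orthonormal polynomial predictors of ``x`` (zero-mean, unit L2 norm).

    Columns span the degree-1..degree polynomials orthogonalised against the
    intercept, with signs fixed so column j correlates positively with x**j.
    """
    x = np.asarray(x, float)
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; orthogonal polynomials undefined")
    xc = x - x.mean()
    M = np.column_stack([np.ones_like(xc)] + [xc**j for j in range(1, degree + 1)])
    Q, _ = np.linalg.qr(M)
    P = Q[:, 1:]
    for j in range(degree):
        if P[:, j] @ (xc ** (j + 1)) < 0:
            P[:, j] = -P[:, j]
    return P


@dataclass(frozen=True)
class BmiRegressionResult:
    """OLS of a per-subject measure on orthogonal BMI and BMI² predictors."""

    beta_bmi: float  # standardized coefficient on the linear predictor
    beta_bmi2: float  # standardized coefficient on the quadratic predictor
    p_bmi: float
    p_bmi2: float
    adj_r2: float
    f_stat: float
    f_p: float
    df_model: int
    df_resid: int


def bmi_polynomial_regression(
    values: np.ndarray, bmi: np.ndarray
) -> BmiRegressionResult:
    """Linear + quadratic BMI regression with orthogonal polynomial predictors.

    Coefficients are standardized (predictor SD over outcome SD), so they are
    comparable across measures; the two predictors are uncorrelated by
    construction.
    """
    y = np.asarray(values, float)
    x = np.asarray(bmi, float)
    if len(y) < 4:
        raise ValueError("regression requires at least 4 subjects")
    P = orthogonal_poly(x, 2)
    X = sm.add_constant(P)
    fit = sm.OLS(y, X).fit()
    sd_y = y.std(ddof=1)
    sd_p = P.std(axis=0, ddof=1)
    beta_std = fit.params[1:] * sd_p / sd_y if sd_y > 0 else np.zeros(2)
    return BmiRegressionResult(
        beta_bmi=float(beta_std[0]),
        beta_bmi2=float(beta_std[1]),
        p_bmi=float(fit.pvalues[1]),
        p_bmi2=float(fit.pvalues[2]),
        adj_r2=float(fit.rsquared_adj),
        f_stat=float(fit.fvalue),
        f_p=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
    )


def normality_variance_screen(
    values: np.ndarray, groups: np.ndarray
) -> pd.DataFrame:
    """Shapiro–Wilk per group plus Levene across groups (screening utility).

    Routing to parametric vs. rank tests stays with the caller; this only
    reports the diagnostics.
    """
    values = np.asarray(values, float)
    groups = np.asarray([str(g) for g in groups])
    labels = list(dict.fromkeys(groups))
    rows = []
    for g in labels:
        w, p = st.shapiro(values[groups == g])
        rows.append({"test": "shapiro", "group": g, "stat": float(w), "p": float(p)})
    w, p = st.levene(*[values[groups == g] for g in labels])
    rows.append({"test": "levene", "group": "all", "stat": float(w), "p": float(p)})
    return pd.DataFrame(rows)


def accumulated_reward(session: SessionData) -> int:
    """Number of rewarded trials in a session (overall performance measure)."""
    return int(session.reward.sum())


def accumulated_reward_analysis(
    sessions: list[SessionData],
    stay: pd.DataFrame | None = None,
    omegas: np.ndarray | None = None,
) -> dict:
    """Group comparison of accumulated reward and its correlations.

    Returns the cohort mean/SD, a one-way group ANOVA (F, p), and Pearson
    correlations with the two contrast scores and, if provided, ω.
    """
    totals = np.array([accumulated_reward(s) for s in sessions], float)
    groups = np.array([str(s.group) for s in sessions])
    out: dict = {
        "mean": float(totals.mean()),
        "sd": float(totals.std(ddof=1)),
        "group_means": {
            g: float(totals[groups == g].mean()) for g in dict.fromkeys(groups)
        },
    }
    if len(set(groups)) >= 2:
        F, p = st.f_oneway(*[totals[groups == g] for g in dict.fromkeys(groups)])
        out["anova"] = {"F": float(F), "p": float(p)}
    corr = {}
    if stay is not None:
        for col in ("interaction_term", "reward_main_term"):
            r, p = st.pearsonr(totals, stay[col].to_numpy(float))
            corr[col] = {"r": float(r), "p": float(p)}
    if omegas is not None:
        r, p = st.pearsonr(totals, np.asarray(omegas, float))
        corr["omega"] = {"r": float(r), "p": float(p)}
    if corr:
        out["correlations"] = corr
    return out
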