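"""Psychometric evaluation of repeated mobile cognitive testing data.

All analyses operate on a tidy *long table* with one row per scheduled
test administration:

    participant_id, group (BD/HV), day (1-14), session_idx, window,
    test_id, phase ('' or short_delay/long_delay for the list-memory
    test), completed (bool), score, rt

and cover: adherence; the mixed-effects logistic *fatigue* model
(missing a test vs study day); linear/Poisson mixed *practice* models
with the interaction-drop rule; piecewise-linear spline changepoints
("stabilization day"); intraindividual variability via the mean square
of successive differences (MSSD); one-way random-effects ICC;
transform-standardize-average composite scores; Levene-gated two-sample
comparisons with Cohen's d; Pearson convergent-validity correlations
against a laboratory battery; and within-person forgetting on the
list-memory test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .glmm import SeparationError, fit_glmm_ri

#: (test_id, outcome) pairs analysed throughout; 'rt' uses the session's
#: secondary reaction-time summary, 'score' its primary score.
ANALYSIS_OUTCOMES: list[tuple[str, str]] = [
    ("matching_pair", "score"),
    ("memory_matrix", "score"),
    ("odd_one_out", "score"),
    ("odd_one_out", "rt"),
    ("vlmt", "score"),
    ("quick_tap1", "score"),
    ("quick_tap2", "score"),
    ("copykat", "score"),
    ("copykat", "rt"),
]

#: Aggregate variable names (per-participant means) used by the
#: composite and validity analyses.
AGG_VARIABLES = [
    "matching_pair", "memory_matrix", "odd_one_out_total", "odd_one_out_rt",
    "vlmt", "quick_tap1_rt", "quick_tap2", "copykat_total", "copykat_rt",
]


# ---------------------------------------------------------------------------
# model-result containers
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    formula: str
    family: str                      # gaussian / poisson / binomial-logit
    effects: dict                    # name -> {estimate, se, p}
    re_var: float
    n_obs: int
    converged: bool
    aic: float = float("nan")
    extra: dict = field(default_factory=dict)

    def estimate(self, name: str) -> float:
        return self.effects[name]["estimate"]

    def p(self, name: str) -> float:
        return self.effects[name]["p"]

    def to_dict(self) -> dict:
        return {
            "formula": self.formula, "family": self.family,
            "effects": self.effects, "re_var": self.re_var,
            "n_obs": self.n_obs, "converged": self.converged,
            "aic": self.aic, **self.extra,
        }


@dataclass
class PracticeFit:
    test_id: str
    outcome: str
    interaction_p: float
    interaction_retained: bool
    final: ModelFit                  # pooled day model, or the interaction model
    group_slopes: Optional[dict] = None   # group -> {estimate, se, p}

    @property
    def day_p(self) -> float:
        return self.final.p("day")

    def to_dict(self) -> dict:
        d = {
            "test_id": self.test_id, "outcome": self.outcome,
            "interaction_p": self.interaction_p,
            "interaction_retained": self.interaction_retained,
            "final": self.final.to_dict(),
        }
        if self.group_slopes is not None:
            d["group_slopes"] = self.group_slopes
        return d


@dataclass
class SplineFit:
    knot_day: Optional[int]          # None = linear-fit sentinel
    pre_slope: float
    pre_se: float
    pre_p: float
    post_slope: float
    post_se: float
    post_p: float
    aic: float
    linear_aic: float

    @property
    def stabilized(self) -> bool:
        """Performance stabilized: post-knot slope not significant at .05."""
        return self.knot_day is not None and self.post_p >= 0.05

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("knot_day", "pre_slope", "pre_se", "pre_p", "post_slope",
                 "post_se", "post_p", "aic", "linear_aic", "stabilized")}


@dataclass
class GroupComparison:
    t: float
    df: float
    p: float
    cohen_d: float
    levene_p: float
    equal_var: bool
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("t", "df", "p", "cohen_d", "levene_p", "equal_var",
                 "mean_a", "mean_b", "n_a", "n_b")}


# ---------------------------------------------------------------------------
# adherence & fatigue
# ---------------------------------------------------------------------------

def adherence(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Percentage of scheduled administrations completed, per participant.

    Returns the per-participant table and a summary with the overall
    mean/SD/range and (when two groups are present) an independent
    t-test of the group difference.
    """
    if len(table) == 0:
        raise ValueError("empty long table: adherence undefined")
    per = (
        table.groupby(["participant_id", "group"], observed=True)["completed"]
        .agg(n_scheduled="size", n_completed="sum")
        .reset_index()
    )
    per["adherence_pct"] = 100.0 * per["n_completed"] / per["n_scheduled"]
    vals = per["adherence_pct"].to_numpy()
    summary = {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
        "range": (float(vals.min()), float(vals.max())),
        "n_completed_total": int(per["n_completed"].sum()),
    }
    if per["group"].nunique() == 2:
        try:
            cmp = group_compare(vals, per["group"].to_numpy())
            summary["group_test"] = cmp.to_dict()
        except ValueError:
            pass  # a group with < 2 participants: comparison undefined
    return per, summary


def fit_fatigue_model(
    table: pd.DataFrame,
    include_group: bool = False,
    level: str = "test",
) -> ModelFit:
    """Mixed-effects logistic regression of missingness on study day.

    Models logit P(missed) = b0 + b1*day with a participant random
    intercept; the day coefficient is the fatigue log-odds (OR per
    1-day increase).  ``level='session'`` collapses to one row per
    scheduled session (tests within a session share one link).
    ``include_group=True`` adds diagnostic group and its day
    interaction.
    """
    df = table.copy()
    if level == "session":
        df = df.drop_duplicates(["participant_id", "day", "session_idx"])
    missed = (~df["completed"].astype(bool)).astype(float).to_numpy()
    day = df["day"].to_numpy(dtype=float)
    names = ["intercept", "day"]
    cols = [np.ones_like(day), day]
    if include_group:
        grp = _group_indicator(df["group"])
        names += ["group", "day:group"]
        cols += [grp, day * grp]
    X = np.column_stack(cols)
    try:
        res = fit_glmm_ri(missed, X, df["participant_id"].to_numpy(),
                          family="binomial", exog_names=names)
    except SeparationError as exc:
        return ModelFit(
            formula="missed ~ day + (1 | participant)", family="binomial-logit",
            effects={}, re_var=float("nan"), n_obs=len(df), converged=False,
            extra={"separation": str(exc)},
        )
    effects = res.summary_dict()["fixed_effects"]
    b = effects["day"]["estimate"]
    se = effects["day"]["se"]
    extra = {
        "odds_ratio_day": float(np.exp(b)),
        "odds_ratio_ci95": (float(np.exp(b - 1.96 * se)),
                            float(np.exp(b + 1.96 * se))),
        "level": level,
    }
    rhs = "day * group" if include_group else "day"
    return ModelFit(
        formula=f"missed ~ {rhs} + (1 | participant)", family="binomial-logit",
        effects=effects, re_var=res.re_sd ** 2, n_obs=res.n_obs,
        converged=res.converged, aic=res.aic, extra=extra,
    )


# ---------------------------------------------------------------------------
# practice-effect mixed models
# ---------------------------------------------------------------------------

def _completed_outcome(table, test_id, outcome, phase=None):
    df = table[(table["test_id"] == test_id) & table["completed"].astype(bool)]
    if test_id == "vlmt":
        phase = phase or "short_delay"
        df = df[df["phase"] == phase]
    col = "score" if outcome == "score" else "rt"
    df = df.dropna(subset=[col])
    return df, col


def _group_indicator(groups: pd.Series) -> np.ndarray:
    # HV coded 1, BD (or the alphabetically first level) 0
    levels = sorted(groups.unique())
    ref = levels[0]
    return (groups != ref).to_numpy(dtype=float)


def _fit_mixedlm(y, X, groups, names, re_day=None) -> ModelFit:
    """Gaussian mixed model via statsmodels MixedLM (ML, not REML).

    ``re_day`` optionally adds a random day slope; on singular or
    non-converged fits the caller falls back to a random intercept.
    """
    exog_re = None if re_day is None else np.column_stack([np.ones_like(re_day), re_day])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
        res = model.fit(reml=False, method="lbfgs", maxiter=200)
    effects = {}
    for i, name in enumerate(names):
        effects[name] = {
            "estimate": float(res.fe_params[i]),
            "se": float(res.bse_fe[i]),
            "p": float(res.pvalues[i]),
        }
    re_var = float(np.atleast_2d(res.cov_re)[0, 0])
    singular = re_day is not None and np.linalg.det(np.atleast_2d(res.cov_re)) < 1e-10
    return ModelFit(
        formula="", family="gaussian", effects=effects, re_var=re_var,
        n_obs=int(res.nobs), converged=bool(res.converged) and not singular,
        aic=float(res.aic),
    )


def _fit_gaussian(df, col, names, design_cols, random_slope_rule=True) -> ModelFit:
    y = df[col].to_numpy(dtype=float)
    X = np.column_stack(design_cols)
    groups = df["participant_id"].to_numpy()
    day = df["day"].to_numpy(dtype=float)
    obs_per = len(df) / max(df["participant_id"].nunique(), 1)
    if random_slope_rule and obs_per >= 5:
        try:
            fit = _fit_mixedlm(y, X, groups, names, re_day=day)
            if fit.converged:
                fit.extra["random_slope"] = True
                return fit
        except Exception:
            pass
    fit = _fit_mixedlm(y, X, groups, names)
    fit.extra["random_slope"] = False
    return fit


def _fit_family(df, col, names, design_cols, family) -> ModelFit:
    if family == "gaussian":
        return _fit_gaussian(df, col, names, design_cols)
    res = fit_glmm_ri(df[col].to_numpy(dtype=float), np.column_stack(design_cols),
                      df["participant_id"].to_numpy(), family="poisson",
                      exog_names=names)
    s = res.summary_dict()
    return ModelFit(formula="", family="poisson", effects=s["fixed_effects"],
                    re_var=res.re_sd ** 2, n_obs=res.n_obs,
                    converged=res.converged, aic=res.aic)


def fit_practice_model(
    table: pd.DataFrame,
    test_id: str,
    outcome: str = "score",
    phase: Optional[str] = None,
    alpha: float = 0.05,
) -> PracticeFit:
    """Mixed-model practice effect for one test outcome.

    Fits score ~ day * group with participant random effects, then
    applies the selection rule: if the day-by-group interaction is not
    significant at ``alpha``, group and the interaction are removed and
    the pooled day slope is reported; otherwise the interaction model is
    kept and within-group day slopes are reported from per-group refits.
    The count-scored Odd One Out total uses a Poisson mixed model; all
    other outcomes are Gaussian.
    """
    df, col = _completed_outcome(table, test_id, outcome, phase)
    if df["participant_id"].nunique() < 3 or df["day"].nunique() < 2:
        raise ValueError(f"too little data to fit practice model for {test_id}")
    family = "poisson" if (test_id == "odd_one_out" and outcome == "score") else "gaussian"
    day = df["day"].to_numpy(dtype=float)
    ones = np.ones_like(day)

    interaction_p = float("nan")
    has_groups = df["group"].nunique() == 2
    if has_groups:
        grp = _group_indicator(df["group"])
        full = _fit_family(df, col, ["intercept", "day", "group", "day:group"],
                           [ones, day, grp, day * grp], family)
        interaction_p = full.p("day:group")
        if interaction_p < alpha:
            slopes = {}
            for gname, gdf in df.groupby("group", observed=True):
                gday = gdf["day"].to_numpy(dtype=float)
                gfit = _fit_family(gdf, col, ["intercept", "day"],
                                   [np.ones_like(gday), gday], family)
                slopes[str(gname)] = gfit.effects["day"]
            full.formula = f"{col} ~ day * group + (1 | participant)"
            return PracticeFit(test_id, outcome, interaction_p, True, full, slopes)

    pooled = _fit_family(df, col, ["intercept", "day"], [ones, day], family)
    pooled.formula = f"{col} ~ day + (1 | participant)"
    return PracticeFit(test_id, outcome, interaction_p, False, pooled)


# ---------------------------------------------------------------------------
# spline changepoint (stabilization day)
# ---------------------------------------------------------------------------

def fit_spline_changepoint(
    table: pd.DataFrame,
    test_id: str,
    outcome: str = "score",
    candidate_knots: Iterable[int] = range(2, 14),
    phase: Optional[str] = None,
    group: Optional[str] = None,
) -> SplineFit:
    """Piecewise-linear mixed model locating the day performance stabilizes.

    For each candidate knot day k the model uses the continuous basis
    s1 = min(day, k), s2 = max(day - k, 0) with a participant random
    intercept; the knot with the smallest (ML) AIC is selected and the
    pre-/post-knot segment slopes reported.  If no knot improves on the
    plain linear trend, a linear-fit sentinel (knot_day=None) is
    returned.  ``group`` restricts the fit to one diagnostic group, as
    used when a practice effect is group-specific.
    """
    df, col = _completed_outcome(table, test_id, outcome, phase)
    if group is not None:
        df = df[df["group"] == group]
    y = df[col].to_numpy(dtype=float)
    day = df["day"].to_numpy(dtype=float)
    groups = df["participant_id"].to_numpy()
    ones = np.ones_like(day)

    linear = _fit_mixedlm(y, np.column_stack([ones, day]), groups,
                          ["intercept", "day"])
    best = None
    for k in candidate_knots:
        s1 = np.minimum(day, float(k))
        s2 = np.maximum(day - float(k), 0.0)
        try:
            fit = _fit_mixedlm(y, np.column_stack([ones, s1, s2]), groups,
                               ["intercept", "pre", "post"])
        except Exception:
            continue
        if best is None or fit.aic < best[1].aic:
            best = (k, fit)

    if best is None or best[1].aic >= linear.aic:
        d = linear.effects["day"]
        return SplineFit(None, d["estimate"], d["se"], d["p"],
                         d["estimate"], d["se"], d["p"],
                         linear.aic, linear.aic)
    k, fit = best
    pre, post = fit.effects["pre"], fit.effects["post"]
    return SplineFit(int(k), pre["estimate"], pre["se"], pre["p"],
                     post["estimate"], post["se"], post["p"],
                     fit.aic, linear.aic)


# ---------------------------------------------------------------------------
# intraindividual variability & reliability
# ---------------------------------------------------------------------------

def mssd(series: Sequence[float]) -> float:
    """Mean square of successive differences.

    sum_i (x_{i+1} - x_i)^2 / (2 (n - 1)) over the chronologically
    ordered non-missing observations; missing sessions are skipped so
    the surviving neighbours are treated as consecutive.  Undefined
    (NaN) for fewer than 2 observations.
    """
    x = np.asarray([v for v in series if v is not None and not np.isnan(v)],
                   dtype=float)
    n = len(x)
    if n < 2:
        return float("nan")
    return float(np.sum(np.diff(x) ** 2) / (2.0 * (n - 1)))


def mssd_by_participant(
    table: pd.DataFrame, test_id: str, outcome: str = "score",
    phase: Optional[str] = None,
) -> pd.DataFrame:
    """Per-participant MSSD of one test outcome, in session order."""
    df, col = _completed_outcome(table, test_id, outcome, phase)
    df = df.sort_values(["participant_id", "day", "session_idx"])
    rows = []
    for (pid, grp), g in df.groupby(["participant_id", "group"], observed=True):
        rows.append({"participant_id": pid, "group": grp,
                     "mssd": mssd(g[col].to_numpy()), "n_obs": len(g)})
    return pd.DataFrame(rows)


def icc_oneway(values: Sequence[float], subjects: Sequence) -> float:
    """One-way random-effects ICC(1) from an ANOVA decomposition.

    Uses the unbalanced-design average cluster size
    k0 = (N - sum(k_i^2)/N) / (n - 1).  Can be negative when
    within-person variance dominates; the raw value is returned
    untruncated so degenerate reliability is visible to the caller.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "s": np.asarray(subjects)}).dropna()
    ns = df.groupby("s")["y"].count()
    ns = ns[ns >= 1]
    n = len(ns)
    N = int(ns.sum())
    if n < 2 or N <= n:
        return float("nan")
    grand = df["y"].mean()
    means = df.groupby("s")["y"].mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((df["y"] - df["s"].map(means)) ** 2).sum())
    msb = ssb / (n - 1)
    msw = ssw / (N - n)
    k0 = (N - float((ns ** 2).sum()) / N) / (n - 1)
    denom = msb + (k0 - 1) * msw
    if denom <= 0 or msw < 0:
        return float("nan")
    return float((msb - msw) / denom)


def icc(table: pd.DataFrame, test_id: str, group: Optional[str] = None,
        outcome: str = "score", phase: Optional[str] = None) -> float:
    df, col = _completed_outcome(table, test_id, outcome, phase)
    if group is not None:
        df = df[df["group"] == group]
    return icc_oneway(df[col], df["participant_id"])


# ---------------------------------------------------------------------------
# aggregation, composite, comparisons, validity
# ---------------------------------------------------------------------------

def aggregate_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean performance on each analysis variable.

    Produces one row per participant with columns named by
    :data:`AGG_VARIABLES` (e.g. ``odd_one_out_rt`` is the mean
    reaction time, ``vlmt`` the mean short-delay recognition score).
    """
    out = table[["participant_id", "group"]].drop_duplicates().set_index("participant_id")
    specs = {
        "matching_pair": ("matching_pair", "score", None),
        "memory_matrix": ("memory_matrix", "score", None),
        "odd_one_out_total": ("odd_one_out", "score", None),
        "odd_one_out_rt": ("odd_one_out", "rt", None),
        "vlmt": ("vlmt", "score", "short_delay"),
        "quick_tap1_rt": ("quick_tap1", "score", None),
        "quick_tap2": ("quick_tap2", "score", None),
        "copykat_total": ("copykat", "score", None),
        "copykat_rt": ("copykat", "rt", None),
    }
    for var, (tid, outcome, phase) in specs.items():
        df, col = _completed_outcome(table, tid, outcome, phase)
        out[var] = df.groupby("participant_id")[col].mean()
    return out.reset_index()


@dataclass
class CompositeSpec:
    """Which aggregate variables enter the composite and how.

    Positively skewed variables are log-transformed, negatively skewed
    ones squared; the ceiling-affected variables are excluded; reversed
    (time-based) variables have their Z-scores negated so a higher
    composite always means better performance.
    """
    log_set: tuple = ("copykat_rt", "odd_one_out_rt", "quick_tap1_rt",
                      "copykat_total")
    square_set: tuple = ("matching_pair", "memory_matrix", "vlmt")
    excluded: tuple = ("odd_one_out_total", "quick_tap2")
    reversed_vars: tuple = ("copykat_rt", "odd_one_out_rt", "quick_tap1_rt")

    def __post_init__(self):
        overlap = set(self.log_set) & set(self.square_set)
        if overlap:
            raise ValueError(f"variables in both transform sets: {overlap}")


def build_composite(
    aggregated: pd.DataFrame, spec: CompositeSpec | None = None
) -> pd.DataFrame:
    """Transform, standardize, orient, and average into a composite.

    Returns the input with added ``z_<var>`` columns and a
    ``composite`` column (mean of available oriented Z-scores; NaN when
    a participant has no included variables).
    """
    spec = spec or CompositeSpec()
    out = aggregated.copy()
    included = [v for v in (*spec.log_set, *spec.square_set) if v in out.columns]
    zcols = []
    for var in included:
        x = out[var].astype(float)
        if var in spec.log_set:
            x = np.log(x.where(x > 0))
        else:
            x = x ** 2
        z = (x - x.mean()) / x.std(ddof=1)
        if var in spec.reversed_vars:
            z = -z
        out[f"z_{var}"] = z
        zcols.append(f"z_{var}")
    out["composite"] = out[zcols].mean(axis=1)
    return out


def group_compare(
    values: Sequence[float], groups: Sequence, order: Optional[tuple] = None
) -> GroupComparison:
    """Independent two-sample comparison with a Levene variance gate.

    Uses the pooled-variance t-test unless Levene's test rejects
    equality of variances at .05, in which case Welch's test is used.
    Cohen's d always uses the pooled SD.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "g": np.asarray(groups)}).dropna()
    levels = list(order) if order else sorted(df["g"].unique())
    if len(levels) != 2:
        raise ValueError("group_compare requires exactly two groups")
    a = df.loc[df["g"] == levels[0], "y"].to_numpy()
    b = df.loc[df["g"] == levels[1], "y"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        lev_p = 1.0
    else:
        lev_p = float(stats.levene(a, b).pvalue)
    equal_var = lev_p >= 0.05
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    n1, n2 = len(a), len(b)
    if equal_var:
        dfree = n1 + n2 - 2
    else:
        v1, v2 = a.var(ddof=1) / n1, b.var(ddof=1) / n2
        dfree = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    d = (a.mean() - b.mean()) / np.sqrt(sp2) if sp2 > 0 else float("nan")
    return GroupComparison(float(t), float(dfree), float(p), float(d),
                           lev_p, equal_var, float(a.mean()), float(b.mean()),
                           n1, n2)


def validity_correlations(
    aggregated: pd.DataFrame,
    battery: pd.DataFrame,
    by_group: bool = True,
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson correlations between mobile aggregates and battery scores.

    ``battery`` holds one row per participant with named standard-score
    columns (e.g. NIH Toolbox age-corrected scores).  Returns a tidy
    frame (group, mobile, battery, r, p, n); cells with fewer than
    ``min_n`` complete pairs are NaN.
    """
    merged = aggregated.merge(battery, on="participant_id", how="inner")
    mobile_vars = [v for v in AGG_VARIABLES + ["composite"] if v in merged.columns]
    battery_vars = [c for c in battery.columns if c != "participant_id"]
    groups = sorted(merged["group"].unique()) if by_group else ["all"]
    rows = []
    for g in groups:
        sub = merged if g == "all" else merged[merged["group"] == g]
        for mv in mobile_vars:
            for bv in battery_vars:
                pair = sub[[mv, bv]].dropna()
                if len(pair) >= min_n:
                    r, p = stats.pearsonr(pair[mv], pair[bv])
                else:
                    r, p = float("nan"), float("nan")
                rows.append({"group": g, "mobile": mv, "battery": bv,
                             "r": float(r), "p": float(p), "n": len(pair)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# list-memory forgetting
# ---------------------------------------------------------------------------

def forgetting_analysis(
    table: pd.DataFrame, demographics: Optional[pd.DataFrame] = None
) -> dict:
    """Within-person words lost from short- to long-delay recognition.

    Pairs the two recognition scores of each day's list; loss =
    short - long (negative values are words gained).  Reports the
    per-participant mean loss, the overall mean/SD/range, a group
    t-test, and (if ``demographics`` is given) per-predictor simple
    OLS regressions of mean loss on each demographic column.
    """
    v = table[(table["test_id"] == "vlmt") & table["completed"].astype(bool)]
    short = v[v["phase"] == "short_delay"][["participant_id", "group", "day", "score"]]
    long = v[v["phase"] == "long_delay"][["participant_id", "day", "score"]]
    pairs = short.merge(long, on=["participant_id", "day"],
                        suffixes=("_short", "_long")).dropna()
    if len(pairs) == 0:
        return {"n_pairs": 0, "flag": "no short/long pairs available"}
    pairs["loss"] = pairs["score_short"] - pairs["score_long"]
    per = (pairs.groupby(["participant_id", "group"], observed=True)["loss"]
           .mean().reset_index(name="mean_loss"))
    vals = per["mean_loss"].to_numpy()
    out = {
        "n_pairs": int(len(pairs)),
        "mean_words_lost": float(pairs["loss"].mean()),
        "sd_words_lost": float(pairs["loss"].std(ddof=1)),
        "range_words_lost": (float(pairs["loss"].min()), float(pairs["loss"].max())),
        "per_participant": per,
    }
    if per["group"].nunique() == 2:
        out["group_test"] = group_compare(vals, per["group"].to_numpy()).to_dict()
    if demographics is not None:
        preds = {}
        merged = per.merge(demographics, on="participant_id", how="inner")
        for c in demographics.columns:
            if c == "participant_id" or not np.issubdtype(merged[c].dtype, np.number):
                continue
            X = sm.add_constant(merged[c].to_numpy(dtype=float))
            res = sm.OLS(merged["mean_loss"].to_numpy(), X).fit()
            preds[c] = {"b": float(res.params[1]), "se": float(res.bse[1]),
                        "p": float(res.pvalues[1])}
        out["demographic_predictors"] = preds
    return out


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

def analyze_study(
    table: pd.DataFrame,
    battery: Optional[pd.DataFrame] = None,
    spline_when_significant: bool = True,
) -> dict:
    """Run the complete psychometric pipeline and return a report dict.

    Sections: adherence, fatigue model, per-outcome practice models
    (with spline stabilization when a significant practice trend is
    found), MSSD group tests, per-group ICCs, the group-comparison
    table over all mobile outcomes, composite scores, list-memory
    forgetting, and (when a battery table is supplied) validity
    correlations.
    """
    report: dict = {}
    per_adh, adh_summary = adherence(table)
    report["adherence"] = adh_summary
    report["fatigue"] = fit_fatigue_model(table).to_dict()
    two_groups = table["group"].nunique() == 2
    if two_groups:
        report["fatigue_by_group"] = fit_fatigue_model(table, include_group=True).to_dict()

    tests_section = {}
    for test_id, outcome in ANALYSIS_OUTCOMES:
        key = f"{test_id}_{outcome}"
        entry: dict = {}
        try:
            pf = fit_practice_model(table, test_id, outcome)
            entry["practice"] = pf.to_dict()
            significant = (pf.interaction_retained or pf.day_p < 0.05)
            if spline_when_significant and significant:
                entry["spline"] = fit_spline_changepoint(table, test_id, outcome).to_dict()
        except Exception as exc:  # degenerate inputs flagged, not fatal
            entry["practice"] = {"flag": f"not fit: {exc}"}
        mt = mssd_by_participant(table, test_id, outcome)
        entry["mssd_mean"] = float(mt["mssd"].mean())
        if two_groups and mt["group"].nunique() == 2:
            try:
                entry["mssd_group_test"] = group_compare(
                    mt["mssd"], mt["group"]).to_dict()
            except ValueError:
                pass
        entry["icc"] = {g: icc(table, test_id, group=g, outcome=outcome)
                        for g in sorted(table["group"].unique())}
        tests_section[key] = entry
    report["tests"] = tests_section

    agg = aggregate_scores(table)
    composed = build_composite(agg)
    report["composite_mean"] = float(composed["composite"].mean())
    if two_groups:
        comparisons = {}
        for var in AGG_VARIABLES + ["composite"]:
            sub = composed[["group", var]].dropna()
            if sub["group"].nunique() == 2 and sub.groupby("group")[var].count().min() >= 2:
                comparisons[var] = group_compare(sub[var], sub["group"]).to_dict()
        report["group_comparisons"] = comparisons

    forg = forgetting_analysis(table)
    forg.pop("per_participant", None)
    report["forgetting"] = forg

    if battery is not None:
        report["validity"] = validity_correlations(composed, battery).to_dict("records")
    else:
        report["validity"] = "skipped: no battery table supplied"
    report["n_participants"] = int(table["participant_id"].nunique())
    return report
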