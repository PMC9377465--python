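"""Psychometric pipeline: each statistic against hand/oracle computations."""

import math

import numpy as np
import pandas as pd
import pytest

from emcog import (
    CompositeSpec,
    adherence,
    aggregate_scores,
    analyze_study,
    build_composite,
    fit_fatigue_model,
    fit_practice_model,
    fit_spline_changepoint,
    forgetting_analysis,
    group_compare,
    icc,
    icc_oneway,
    mssd,
    mssd_by_participant,
    validity_correlations,
)
from emcog.simulate import simulate_score_trajectories


def _long_rows(pid, group, scores, test_id="matching_pair", completed=None,
               phase=""):
    completed = completed or [True] * len(scores)
    return [
        {"participant_id": pid, "group": group, "day": d + 1,
         "session_idx": d + 1, "window": "MA", "test_id": test_id,
         "phase": phase, "completed": c,
         "score": s if c else float("nan"), "rt": float("nan")}
        for d, (s, c) in enumerate(zip(scores, completed))
    ]


# ---------------------------------------------------------------------------
# adherence
# ---------------------------------------------------------------------------

def test_adherence_direct_division():
    rows = []
    comp = [True] * 29 + [False] * 13          # 29 of 42
    rows += _long_rows("a", "BD", list(range(42)), completed=comp)
    rows += _long_rows("b", "HV", list(range(42)))
    per, summary = adherence(pd.DataFrame(rows))
    a = per.set_index("participant_id")
    assert a.loc["a", "adherence_pct"] == pytest.approx(100 * 29 / 42)
    assert a.loc["b", "adherence_pct"] == 100.0
    assert summary["mean"] == pytest.approx((100 * 29 / 42 + 100) / 2)


# ---------------------------------------------------------------------------
# fatigue model
# ---------------------------------------------------------------------------

def test_fatigue_model_null_slope_covered():
    rng = np.random.default_rng(0)
    rows = []
    for i in range(40):
        comp = list(rng.random(42) > 0.3)
        rows += _long_rows(f"p{i}", "BD" if i < 25 else "HV",
                           list(range(42)), completed=comp)
    fit = fit_fatigue_model(pd.DataFrame(rows))
    lo, hi = fit.extra["odds_ratio_ci95"]
    assert lo < 1.0 < hi


def test_fatigue_model_separation_flagged():
    rows = _long_rows("a", "BD", range(14)) + _long_rows("b", "BD", range(14))
    fit = fit_fatigue_model(pd.DataFrame(rows))
    assert not fit.converged
    assert "separation" in fit.extra


# ---------------------------------------------------------------------------
# practice models & interaction-drop rule
# ---------------------------------------------------------------------------

def test_practice_noiseless_linear_recovers_exact_slope():
    rows = []
    for i, b0 in enumerate([3.0, 7.0, 11.0, 2.0]):
        rows += _long_rows(f"p{i}", "BD", [b0 + 1.0 * d for d in range(1, 15)])
    pf = fit_practice_model(pd.DataFrame(rows), "matching_pair")
    assert pf.final.estimate("day") == pytest.approx(1.0, abs=1e-3)


def test_interaction_drop_rule_null_case():
    tab = simulate_score_trajectories(slope_bd=0.1, slope_hv=0.1, seed=20)
    pf = fit_practice_model(tab, "matching_pair")
    assert not pf.interaction_retained
    assert pf.interaction_p >= 0.05
    assert "group" not in pf.final.effects  # group dropped entirely


def test_interaction_retained_with_group_specific_slopes():
    tab = simulate_score_trajectories(slope_bd=0.05, slope_hv=0.23, seed=21)
    pf = fit_practice_model(tab, "matching_pair")
    assert pf.interaction_retained
    hv = pf.group_slopes["HV"]
    bd = pf.group_slopes["BD"]
    assert abs(hv["estimate"] - 0.23) < 1.96 * hv["se"] + 1e-9
    assert abs(bd["estimate"] - 0.05) < 1.96 * bd["se"] + 1e-9


def test_model_selection_is_deterministic():
    tab = simulate_score_trajectories(seed=22)
    a = fit_practice_model(tab, "matching_pair")
    b = fit_practice_model(tab, "matching_pair")
    assert a.interaction_p == b.interaction_p
    assert a.interaction_retained == b.interaction_retained
    assert a.final.effects == b.final.effects


def test_poisson_family_used_for_count_scored_symbol_search():
    rng = np.random.default_rng(3)
    rows = []
    for i in range(30):
        lam = np.exp(1.8 + 0.02 * np.arange(1, 15) + rng.normal(0, 0.2))
        scores = rng.poisson(np.clip(lam, 0, 9)).clip(0, 9)
        rows += _long_rows(f"p{i}", "BD" if i % 2 else "HV", list(scores),
                           test_id="odd_one_out")
    pf = fit_practice_model(pd.DataFrame(rows), "odd_one_out", outcome="score")
    assert pf.final.family == "poisson"


# ---------------------------------------------------------------------------
# spline changepoint
# ---------------------------------------------------------------------------

def test_spline_noiseless_piecewise_finds_exact_knot():
    rows = []
    for i, b0 in enumerate([0.0, 4.0, 8.0]):
        scores = [b0 + 0.5 * min(d, 7) + 0.0 * max(d - 7, 0)
                  for d in range(1, 15)]
        scores = [s + 0.001 * ((i + d) % 3) for d, s in enumerate(scores)]
        rows += _long_rows(f"p{i}", "BD", scores)
    sf = fit_spline_changepoint(pd.DataFrame(rows), "matching_pair")
    assert sf.knot_day == 7
    assert sf.pre_slope == pytest.approx(0.5, abs=0.01)
    assert abs(sf.post_slope) < 0.01


def test_spline_flat_data_returns_linear_sentinel():
    rng = np.random.default_rng(30)
    rows = []
    for i in range(12):
        rows += _long_rows(f"p{i}", "BD",
                           list(10.0 + rng.normal(0, 0.05, 14)))
    sf = fit_spline_changepoint(pd.DataFrame(rows), "matching_pair")
    assert sf.knot_day is None or sf.post_p >= 0.05


def test_spline_recovers_day4_changepoint():
    tab = simulate_score_trajectories(slope_bd=0.42, slope_hv=0.42,
                                      knot_day=4, post_slope=0.0,
                                      resid_sd=1.0, seed=31)
    sf = fit_spline_changepoint(tab, "matching_pair")
    assert sf.knot_day in (3, 4, 5)
    assert sf.post_p >= 0.05       # stabilized after the knot
    assert sf.pre_p < 0.001
    assert sf.stabilized


# ---------------------------------------------------------------------------
# MSSD
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "series,expected",
    [
        ([5.0] * 6, 0.0),                       # constant
        ([1, -1, 1, -1, 1], 2.0),               # alternating: diffs^2 = 4
        ([0.0, 3.0], 4.5),                      # 9 / (2*1)
    ],
)
def test_mssd_closed_forms(series, expected):
    assert mssd(series) == pytest.approx(expected)


def test_mssd_undefined_below_two_observations():
    assert math.isnan(mssd([3.0]))
    assert math.isnan(mssd([np.nan, np.nan]))


def test_mssd_skips_missing_sessions():
    assert mssd([1.0, np.nan, 2.0]) == mssd([1.0, 2.0])


def test_mssd_by_participant_orders_chronologically():
    rows = _long_rows("a", "BD", [1, 3, 1, 3])
    out = mssd_by_participant(pd.DataFrame(rows), "matching_pair")
    assert out.loc[0, "mssd"] == pytest.approx(4 * 3 / (2 * 3))


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def test_icc_hand_anova_oracle():
    # participants A:(1,2), B:(5,6): MSB=16, MSW=0.5, k0=2
    vals = [1, 2, 5, 6]
    subs = ["A", "A", "B", "B"]
    expected = (16 - 0.5) / (16 + (2 - 1) * 0.5)
    assert icc_oneway(vals, subs) == pytest.approx(expected)


def test_icc_extremes():
    # all between-person variance, zero within
    assert icc_oneway([1, 1, 8, 8, 4, 4], ["a", "a", "b", "b", "c", "c"]) == \
        pytest.approx(1.0)
    # zero between-person variance: raw ICC is negative (documented)
    assert icc_oneway([0, 1, 0, 1], ["a", "a", "b", "b"]) <= 0


def test_icc_from_long_table(small_study):
    _, data, _ = small_study
    val = icc(data.long_table, "memory_matrix", group="BD")
    assert -1.0 <= val <= 1.0


# ---------------------------------------------------------------------------
# composite
# ---------------------------------------------------------------------------

def _toy_aggregates(n=20, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "participant_id": [f"p{i}" for i in range(n)],
        "group": ["BD" if i % 2 else "HV" for i in range(n)],
        "matching_pair": rng.uniform(200, 600, n),
        "memory_matrix": rng.uniform(10, 60, n),
        "odd_one_out_total": rng.uniform(5, 9, n),
        "odd_one_out_rt": rng.uniform(1, 4, n),
        "vlmt": rng.uniform(12, 24, n),
        "quick_tap1_rt": rng.uniform(0.3, 0.9, n),
        "quick_tap2": rng.uniform(7, 12, n),
        "copykat_total": rng.uniform(3, 15, n),
        "copykat_rt": rng.uniform(0.5, 2.0, n),
    })
    return df


def test_composite_zero_mean_and_excludes_ceiling_variables():
    out = build_composite(_toy_aggregates())
    assert out["composite"].mean() == pytest.approx(0.0, abs=1e-10)
    assert "z_odd_one_out_total" not in out.columns
    assert "z_quick_tap2" not in out.columns


def test_composite_best_participant_has_max_composite():
    df = _toy_aggregates()
    best = df.index[3]
    for col in ("matching_pair", "memory_matrix", "vlmt", "copykat_total"):
        df.loc[best, col] = df[col].max() + 1
    for col in ("odd_one_out_rt", "quick_tap1_rt", "copykat_rt"):
        df.loc[best, col] = df[col].min() * 0.5
    # copykat_total is log-transformed but not reversed: high = good
    out = build_composite(df)
    assert out["composite"].idxmax() == best


def test_composite_invariant_to_row_and_column_order():
    df = _toy_aggregates()
    a = build_composite(df).set_index("participant_id")["composite"]
    shuffled = df.sample(frac=1.0, random_state=5)[list(df.columns[::-1])]
    b = build_composite(shuffled).set_index("participant_id")["composite"]
    pd.testing.assert_series_equal(a.sort_index(), b.sort_index())


def test_composite_z_step_invariance_on_transformed_values():
    """Affine rescaling AFTER the skew transform cancels in the Z step."""
    df = _toy_aggregates()
    spec = CompositeSpec()
    base = build_composite(df, spec)["composite"]
    df2 = df.copy()
    # squaring then z-scoring: rescale the squared values via sqrt trick
    df2["matching_pair"] = df["matching_pair"] * 3.0   # (3x)^2 = 9 x^2 affine
    alt = build_composite(df2, spec)["composite"]
    pd.testing.assert_series_equal(base, alt)


def test_composite_all_missing_participant_flagged():
    df = _toy_aggregates(n=5)
    for col in df.columns:
        if col not in ("participant_id", "group"):
            df.loc[2, col] = np.nan
    out = build_composite(df)
    assert math.isnan(out.loc[2, "composite"])


def test_composite_spec_rejects_overlapping_sets():
    with pytest.raises(ValueError):
        CompositeSpec(log_set=("vlmt",), square_set=("vlmt",))


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def test_group_compare_identical_groups():
    res = group_compare([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
    assert res.t == pytest.approx(0.0)
    assert res.cohen_d == pytest.approx(0.0)


def test_group_compare_matches_textbook_formulas():
    a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 7.0]
    res = group_compare(a + b, ["x"] * 3 + ["y"] * 3)
    ma, mb = np.mean(a), np.mean(b)
    sa2, sb2 = np.var(a, ddof=1), np.var(b, ddof=1)
    sp2 = (2 * sa2 + 2 * sb2) / 4
    t_hand = (ma - mb) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
    d_hand = (ma - mb) / math.sqrt(sp2)
    assert res.t == pytest.approx(t_hand)
    assert res.cohen_d == pytest.approx(d_hand)
    assert res.df == 4


def test_group_compare_welch_branch_on_heteroscedastic_data():
    rng = np.random.default_rng(7)
    a = rng.normal(0, 0.1, 60)
    b = rng.normal(0.5, 3.0, 60)
    res = group_compare(np.r_[a, b], ["a"] * 60 + ["b"] * 60)
    assert res.levene_p < 0.05
    assert not res.equal_var
    assert res.df < 118  # Welch df shrinks below pooled n1+n2-2


# ---------------------------------------------------------------------------
# validity correlations
# ---------------------------------------------------------------------------

def test_validity_perfect_correlation_with_self():
    agg = _toy_aggregates()
    battery = agg[["participant_id"]].copy()
    battery["fluid"] = agg["vlmt"]
    out = validity_correlations(agg, battery, by_group=False)
    row = out[(out.mobile == "vlmt") & (out.battery == "fluid")].iloc[0]
    assert row.r == pytest.approx(1.0)


def test_validity_matches_closed_form_pearson():
    agg = _toy_aggregates(n=5)
    battery = agg[["participant_id"]].copy()
    battery["lab"] = [2.0, 4.0, 4.0, 7.0, 9.0]
    out = validity_correlations(agg, battery, by_group=False)
    x = agg["matching_pair"].to_numpy()
    y = np.array([2.0, 4.0, 4.0, 7.0, 9.0])
    r_hand = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    row = out[(out.mobile == "matching_pair") & (out.battery == "lab")].iloc[0]
    assert row.r == pytest.approx(r_hand)


def test_validity_small_cells_are_nan():
    agg = _toy_aggregates(n=4)
    agg.loc[1:, "vlmt"] = np.nan
    battery = agg[["participant_id"]].assign(lab=[1.0, 2.0, 3.0, 4.0])
    out = validity_correlations(agg, battery, by_group=False)
    row = out[(out.mobile == "vlmt") & (out.battery == "lab")].iloc[0]
    assert math.isnan(row.r)


# ---------------------------------------------------------------------------
# forgetting
# ---------------------------------------------------------------------------

def test_forgetting_pairs_and_signs():
    rows = []
    rows += _long_rows("a", "BD", [20, 18], test_id="vlmt", phase="short_delay")
    rows += _long_rows("a", "BD", [16, 20], test_id="vlmt", phase="long_delay")
    out = forgetting_analysis(pd.DataFrame(rows))
    # losses: 20-16 = 4 and 18-20 = -2 (words gained allowed)
    assert out["n_pairs"] == 2
    assert out["mean_words_lost"] == pytest.approx(1.0)
    assert out["range_words_lost"] == (-2.0, 4.0)


def test_forgetting_no_pairs_flagged():
    rows = _long_rows("a", "BD", [20], test_id="vlmt", phase="short_delay")
    out = forgetting_analysis(pd.DataFrame(rows))
    assert out["n_pairs"] == 0 and "flag" in out


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

def test_analyze_study_report_structure(small_study):
    _, data, battery = small_study
    report = analyze_study(data.long_table, battery)
    assert {"adherence", "fatigue", "tests", "group_comparisons",
            "forgetting", "validity"} <= set(report)
    # the group table covers all eight mobile outcomes
    eight = {"matching_pair", "odd_one_out_rt", "quick_tap1_rt",
             "memory_matrix", "odd_one_out_total", "copykat_total",
             "vlmt", "quick_tap2"}
    assert eight <= set(report["group_comparisons"])
    assert len(report["tests"]) == 9


def test_analyze_study_single_group_skips_comparisons(small_study):
    _, data, _ = small_study
    lt = data.long_table
    one = lt[lt.group == "BD"]
    report = analyze_study(one)
    assert "group_comparisons" not in report
    assert "adherence" in report and "tests" in report
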