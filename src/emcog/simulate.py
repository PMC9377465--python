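"""Virtual respondents: synthetic cohorts for the psychometric pipeline.

The study being emulated collects repeated mobile cognitive tests from
two diagnostic groups (BD and healthy volunteers, default n = 45 + 21)
over a 14-day, 3-sessions-per-day protocol.  The generator reproduces
the statistical structure the downstream analyses presuppose:

* session-level missingness that is logistic in study day (the
  "fatigue effect", default day log-odds 0.093 with an intercept placed
  so mean adherence sits near 70%),
* a between-group performance gap on a latent ability scale per test
  (defaults anchored to the observed effect sizes),
* per-trial accuracy that is logistic in ability + practice - item
  demand, so adaptive tests equilibrate at ability-dependent spans,
* lognormal reaction times with person-specific speed, a slow practice
  drift, and a wider within-person dispersion in the BD group.

Two generators are exposed.  :func:`simulate_study` runs the actual
test engines trial by trial and emits the tidy long table plus raw
trial logs.  :func:`simulate_score_trajectories` generates session
scores directly from the linear mixed model the practice analysis fits
(known day slopes per group), which is the appropriate ground truth for
parameter-recovery checks of the model-fitting code itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import engines
from .config import EngineConfig
from .scheduler import (
    VLMT_LONG, VLMT_SHORT, VLMT_STUDY, ProtocolSchedule, build_schedule,
)
from .types import TEST_IDS, SessionResult


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# ---------------------------------------------------------------------------
# cohort specification & sampling
# ---------------------------------------------------------------------------

#: Between-group standardized gaps on the latent ability scale, anchored
#: to the effect sizes observed for each test.
DEFAULT_COHEN_D = {
    "matching_pair": 0.53, "memory_matrix": 0.47, "odd_one_out": 0.29,
    "vlmt": 0.53, "quick_tap1": 0.54, "quick_tap2": 0.25, "copykat": 0.39,
}

#: Log-scale reaction-time location (log seconds) per test; Quick Tap is
#: a simple RT (~0.45 s), symbol search ~2 s, sequence steps ~0.9 s.
DEFAULT_SPEED_MU = {
    "matching_pair": math.log(2.2), "memory_matrix": math.log(3.0),
    "odd_one_out": math.log(2.0), "vlmt": math.log(1.5),
    "quick_tap1": math.log(0.45), "quick_tap2": math.log(0.45),
    "copykat": math.log(0.9),
}


@dataclass
class RespondentProfile:
    """Latent parameters of one virtual participant."""

    participant_id: str
    group: str                        # "BD" or "HV"
    ability: dict                     # test -> latent standard-normal ability
    speed_mu: dict                    # test -> log-seconds
    speed_sigma: dict                 # test -> log-seconds (> 0)
    practice_slope: dict              # test -> logit units / day
    rt_practice: dict                 # test -> log-seconds / day speedup
    fatigue_intercept: float          # logit of missing a session at day 0
    fatigue_slope: float              # logit / day
    lapse_prob: float                 # momentary no-response probability
    iiv_scale: float                  # multiplier on trial RT dispersion

    def __post_init__(self):
        if not 0.0 <= self.lapse_prob <= 1.0:
            raise ValueError("lapse_prob must lie in [0, 1]")
        if self.iiv_scale <= 0 or any(s <= 0 for s in self.speed_sigma.values()):
            raise ValueError("dispersion parameters must be positive")

    def miss_prob(self, day: int) -> float:
        return _sigmoid(self.fatigue_intercept + self.fatigue_slope * day)


@dataclass
class CohortSpec:
    """Generative settings for a two-group cohort."""

    n_bd: int = 45
    n_hv: int = 21
    cohen_d: dict = field(default_factory=lambda: dict(DEFAULT_COHEN_D))
    practice_slope_mean: dict = field(
        default_factory=lambda: {"BD": 0.010, "HV": 0.020})  # logit/day
    practice_slope_sd: float = 0.010
    rt_practice_mean: float = 0.005   # log-s/day speedup
    rt_practice_sd: float = 0.003
    fatigue_intercept_mean: float = -1.692  # expected adherence 69.7%
    fatigue_intercept_sd: float = 0.9
    fatigue_slope_mean: float = 0.093      # fatigue log-odds per day
    fatigue_slope_sd: float = 0.0
    lapse_prob: float = 0.02
    iiv_scale: dict = field(default_factory=lambda: {"BD": 1.3, "HV": 1.0})
    speed_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_bd < 0 or self.n_hv < 0:
            raise ValueError("group sizes must be non-negative")
        for d in self.cohen_d.values():
            if not np.isfinite(d):
                raise ValueError("effect sizes must be finite")


def sample_cohort(spec: CohortSpec) -> list[RespondentProfile]:
    """Draw a reproducible cohort of respondent profiles.

    Latent abilities are normal with SD 1 around group means separated
    by the configured d per test (HV above BD by +d).
    """
    rng = np.random.default_rng(spec.seed)
    profiles: list[RespondentProfile] = []
    members = [("BD", i) for i in range(spec.n_bd)] + \
              [("HV", i) for i in range(spec.n_hv)]
    for group, i in members:
        sign = +0.5 if group == "HV" else -0.5
        ability = {t: float(rng.normal(sign * spec.cohen_d.get(t, 0.0), 1.0))
                   for t in TEST_IDS}
        speed_shift = float(rng.normal(0.0, 0.15))
        speed_mu = {t: DEFAULT_SPEED_MU[t] + speed_shift - 0.1 * ability[t]
                    for t in TEST_IDS}
        practice = {t: float(rng.normal(spec.practice_slope_mean[group],
                                        spec.practice_slope_sd))
                    for t in TEST_IDS}
        rt_prac = {t: float(rng.normal(spec.rt_practice_mean, spec.rt_practice_sd))
                   for t in TEST_IDS}
        profiles.append(RespondentProfile(
            participant_id=f"{group.lower()}{i + 1:03d}",
            group=group,
            ability=ability,
            speed_mu=speed_mu,
            speed_sigma={t: spec.speed_sigma for t in TEST_IDS},
            practice_slope=practice,
            rt_practice=rt_prac,
            fatigue_intercept=float(rng.normal(spec.fatigue_intercept_mean,
                                               spec.fatigue_intercept_sd)),
            fatigue_slope=float(rng.normal(spec.fatigue_slope_mean,
                                           spec.fatigue_slope_sd)),
            lapse_prob=spec.lapse_prob,
            iiv_scale=spec.iiv_scale[group],
        ))
    return profiles


# ---------------------------------------------------------------------------
# behavioural responders
# ---------------------------------------------------------------------------

class ProfileResponder:
    """Adapts a respondent profile into per-test responder callables.

    Per-trial accuracy follows a logistic in ability + practice*day
    minus a test-specific item demand; reaction times are lognormal
    with a person/day-specific location.  A momentary lapse produces a
    non-response (or a random guess on forced-choice items).
    """

    # fixed difficulty ladder offsets: sigmoid(base + ability - demand)
    _BASE = {"matching_pair": 3.0, "memory_matrix": 4.5, "odd_one_out": 2.2,
             "vlmt": 0.9, "quick_tap2": 2.0, "copykat": 3.5}
    _LONG_DELAY_PENALTY = 0.7   # logit drop from short to long recognition

    def __init__(self, profile: RespondentProfile, day: int, rng: np.random.Generator):
        self.p = profile
        self.day = day
        self.rng = rng

    # -- helpers ------------------------------------------------------
    def _acc(self, test: str, demand: float = 0.0, weight: float = 1.0) -> float:
        logit = (self._BASE[test] + weight * self.p.ability[test]
                 + self.p.practice_slope[test] * self.day - demand)
        return _sigmoid(logit)

    def _latency(self, test: str, scale: float = 1.0) -> float:
        mu = (self.p.speed_mu[test] - self.p.rt_practice[test] * self.day
              + math.log(scale))
        sigma = self.p.speed_sigma[test] * self.p.iiv_scale
        return float(np.exp(self.rng.normal(mu, sigma)))

    def _lapse(self) -> bool:
        return bool(self.rng.random() < self.p.lapse_prob)

    # -- per-test responders ------------------------------------------
    def matching_pair(self, stim: dict):
        colors = stim["colors"]
        pair = [i for i in range(len(colors))
                if colors.count(colors[i]) == 2]
        lat = self._latency("matching_pair", scale=1 + 0.05 * len(colors))
        if not self._lapse() and self.rng.random() < self._acc("matching_pair"):
            return {"selected": (pair[0], pair[1])}, lat
        wrong = [i for i in range(len(colors)) if i not in pair]
        return {"selected": (pair[0], wrong[0])}, lat

    def memory_matrix(self, stim: dict):
        targets = list(stim["targets"])
        span = len(targets)
        lat = self._latency("memory_matrix", scale=0.3 + 0.15 * span)
        p = self._acc("memory_matrix", demand=0.9 * span, weight=1.2)
        if not self._lapse() and self.rng.random() < p:
            return {"selected": targets}, lat
        # plausible error: swap one target for a neighbour cell
        side = stim["side"]
        others = [c for c in range(side * side) if c not in targets]
        bad = targets[:-1] + [int(self.rng.choice(others))] if others else targets[:-1]
        return {"selected": bad}, lat

    def odd_one_out(self, stim: dict):
        symbols = stim["symbols"]
        odd = next(i for i, s in enumerate(symbols) if symbols.count(s) == 1)
        lat = self._latency("odd_one_out")
        if not self._lapse() and self.rng.random() < self._acc("odd_one_out"):
            return {"selected": odd}, lat
        wrong = int(self.rng.choice([i for i in range(len(symbols)) if i != odd]))
        return {"selected": wrong}, lat

    def vlmt(self, stim: dict):
        if stim.get("phase") == "study":
            return None, stim["study_s"]
        penalty = self._LONG_DELAY_PENALTY if stim["phase"] == "long_delay" else 0.0
        lat = self._latency("vlmt")
        if self._lapse():
            return {"yes": not stim["is_target"]}, lat
        right = self.rng.random() < self._acc("vlmt", demand=penalty, weight=0.6)
        yes = stim["is_target"] if right else not stim["is_target"]
        return {"yes": bool(yes)}, lat

    def quick_tap1(self, stim: dict):
        if self._lapse():
            return None, 0.0  # no tap: timeout
        if self.rng.random() < 0.02:
            return {"tap_latency_s": -float(self.rng.uniform(0.1, stim["onset_s"]))}, 0.0
        return {"tap_latency_s": self._latency("quick_tap1")}, 0.0

    def quick_tap2(self, stim: dict):
        if self._lapse():
            # lapse: impulsive tap on a foil, frozen miss on a target
            if stim["is_foil"]:
                return {"tap_latency_s": self._latency("quick_tap2")}, 0.0
            return None, 0.0
        go_ok = self.rng.random() < self._acc("quick_tap2")
        if stim["is_foil"]:
            if go_ok:
                return None, 0.0          # correctly withheld
            return {"tap_latency_s": self._latency("quick_tap2")}, 0.0
        if not go_ok:
            return None, 0.0              # missed the target
        return {"tap_latency_s": self._latency("quick_tap2")}, 0.0

    def copykat(self, stim: dict):
        seq = list(stim["sequence"])
        lat = len(seq) * self._latency("copykat")
        p = self._acc("copykat", demand=0.35 * len(seq))
        if self._lapse():
            return None, stim["timeout_s"] + 1.0
        if self.rng.random() < p:
            return {"sequence": seq, "elapsed_s": min(lat, stim["timeout_s"])}, lat
        bad = list(seq)
        bad[int(self.rng.integers(len(bad)))] = int(self.rng.integers(4))
        if bad == seq:
            bad.append(0)
        return {"sequence": bad, "elapsed_s": min(lat, stim["timeout_s"])}, lat

    def for_test(self, test_id: str):
        return getattr(self, test_id)


# ---------------------------------------------------------------------------
# full engine-level study simulation
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """Output bundle of :func:`simulate_study`."""

    long_table: pd.DataFrame
    session_rows: list[dict]
    trial_rows: list[dict]
    schedules: dict


_PHASE_OF = {VLMT_SHORT: "short_delay", VLMT_LONG: "long_delay"}


def simulate_study(
    cohort: list[RespondentProfile],
    engine_config: Optional[EngineConfig] = None,
    seed: int = 0,
    wake_time: str = "08:00",
    sleep_time: str = "22:00",
    assignment_table: Optional[dict] = None,
) -> StudyData:
    """Run the full 14-day protocol for every cohort member.

    Each scheduled session is missed with the profile's logistic
    fatigue probability; completed sessions run every assigned engine
    with the profile's responder.  Returns the tidy long table (one row
    per scored administration), flat session/trial records for the CSV
    and JSONL writers, and the per-participant schedules.
    """
    config = engine_config or EngineConfig()
    master = np.random.SeedSequence(seed)
    long_rows: list[dict] = []
    session_rows: list[dict] = []
    trial_rows: list[dict] = []
    schedules = {}

    for profile, ss in zip(cohort, master.spawn(len(cohort))):
        sched_ss, miss_ss, behav_ss, stim_ss = ss.spawn(4)
        schedule = build_schedule(
            profile.participant_id, wake_time, sleep_time, assignment_table,
            seed=int(sched_ss.generate_state(1)[0] % 2**31))
        schedules[profile.participant_id] = schedule
        miss_rng = np.random.default_rng(miss_ss)
        behav_rng = np.random.default_rng(behav_ss)
        stim_rng = np.random.default_rng(stim_ss)
        studied: set[int] = set()

        for day in range(1, 15):
            sessions = schedule.sessions_on(day)
            for s_idx, entry in enumerate(sessions):
                session_idx = (day - 1) * 3 + s_idx + 1
                completed = bool(miss_rng.random() >= profile.miss_prob(day))
                responder = ProfileResponder(profile, day, behav_rng)
                for test in entry.tests:
                    phase = _PHASE_OF.get(test, "")
                    test_id = "vlmt" if test.startswith("vlmt") else test
                    runnable = completed
                    if test == VLMT_LONG and day not in studied:
                        runnable = False  # its study session was missed
                    result: Optional[SessionResult] = None
                    if runnable:
                        eseed = int(stim_rng.integers(2**31))
                        if test == VLMT_STUDY:
                            result = engines.run_vlmt(day, "study",
                                                      responder.vlmt, config, eseed)
                            studied.add(day)
                        elif test in _PHASE_OF:
                            result = engines.run_vlmt(
                                day, _PHASE_OF[test], responder.vlmt, config,
                                eseed, studied_lists=studied)
                        else:
                            result = engines.RUNNERS[test](
                                responder.for_test(test), config, eseed)
                        for tr in result.trials:
                            trial_rows.append({
                                "participant_id": profile.participant_id,
                                "day": day, "session_idx": session_idx,
                                "test_id": test_id, "phase": phase,
                                **tr.to_dict()})
                        session_rows.append(_session_row(
                            profile, day, session_idx, test_id, phase,
                            result, completed=True))
                    else:
                        session_rows.append(_session_row(
                            profile, day, session_idx, test_id, phase,
                            None, completed=False))
                    if test == VLMT_STUDY:
                        continue  # study exposure is not a scored outcome
                    long_rows.append({
                        "participant_id": profile.participant_id,
                        "group": profile.group,
                        "day": day, "session_idx": session_idx,
                        "window": entry.window,
                        "test_id": test_id, "phase": phase,
                        "completed": bool(runnable),
                        "score": result.score if result is not None else float("nan"),
                        "rt": (result.rt_mean_s if result is not None and
                               result.rt_mean_s is not None else float("nan")),
                    })

    return StudyData(pd.DataFrame(long_rows), session_rows, trial_rows, schedules)


def _session_row(profile, day, session_idx, test_id, phase, result, completed):
    if result is None:
        return {"participant_id": profile.participant_id, "group": profile.group,
                "day": day, "session_idx": session_idx, "test_id": test_id,
                "phase": phase, "score": float("nan"), "rt_mean_s": float("nan"),
                "n_trials": 0, "n_correct": 0, "terminated_by": "",
                "completed": False}
    return {"participant_id": profile.participant_id, "group": profile.group,
            "day": day, "session_idx": session_idx, "test_id": test_id,
            "phase": phase, "score": result.score,
            "rt_mean_s": (result.rt_mean_s if result.rt_mean_s is not None
                          else float("nan")),
            "n_trials": result.n_trials, "n_correct": result.n_correct,
            "terminated_by": result.terminated_by, "completed": completed}


# ---------------------------------------------------------------------------
# fast model-based generators (parameter-recovery ground truth)
# ---------------------------------------------------------------------------

def simulate_missingness(
    cohort: list[RespondentProfile], seed: int = 0,
    n_days: int = 14, sessions_per_day: int = 3,
) -> pd.DataFrame:
    """Session-level completion indicators only (no engine runs).

    The completion mechanism is identical to :func:`simulate_study`'s:
    logistic in study day with person-specific intercepts.  Useful when
    only the adherence/fatigue machinery is under test.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in cohort:
        for day in range(1, n_days + 1):
            for s in range(sessions_per_day):
                rows.append({
                    "participant_id": p.participant_id, "group": p.group,
                    "day": day, "session_idx": (day - 1) * sessions_per_day + s + 1,
                    "window": ("MA", "MD", "EE")[s], "test_id": "matching_pair",
                    "phase": "",
                    "completed": bool(rng.random() >= p.miss_prob(day)),
                    "score": float("nan"), "rt": float("nan"),
                })
    return pd.DataFrame(rows)


def simulate_score_trajectories(
    n_bd: int = 45,
    n_hv: int = 21,
    slope_bd: float = 0.05,
    slope_hv: float = 0.23,
    intercept: float = 20.0,
    group_gap: float = 2.0,
    re_sd: float = 3.0,
    resid_sd: float = 2.0,
    days: Optional[list[int]] = None,
    knot_day: Optional[int] = None,
    post_slope: float = 0.0,
    test_id: str = "matching_pair",
    seed: int = 0,
) -> pd.DataFrame:
    """Session scores drawn from the exact linear mixed model.

    score_ij = intercept + gap*1[HV] + b0_i + slope_g * day + e_ij with
    b0_i ~ N(0, re_sd^2) and e_ij ~ N(0, resid_sd^2).  With
    ``knot_day`` set, the day trend is piecewise linear: the group
    slope applies up to the knot and ``post_slope`` after it (the
    changepoint-recovery ground truth).  Returns a long table ready for
    the practice/spline fitters.
    """
    rng = np.random.default_rng(seed)
    days = list(days) if days is not None else list(range(1, 15))
    rows = []
    members = [("BD", i, slope_bd) for i in range(n_bd)] + \
              [("HV", i, slope_hv) for i in range(n_hv)]
    for group, i, slope in members:
        b0 = rng.normal(0.0, re_sd)
        base = intercept + (group_gap if group == "HV" else 0.0) + b0
        for day in days:
            if knot_day is None:
                trend = slope * day
            else:
                trend = slope * min(day, knot_day) + post_slope * max(day - knot_day, 0)
            rows.append({
                "participant_id": f"{group.lower()}{i + 1:03d}", "group": group,
                "day": day, "session_idx": day, "window": "MA",
                "test_id": test_id, "phase": "", "completed": True,
                "score": base + trend + rng.normal(0.0, resid_sd),
                "rt": float("nan"),
            })
    return pd.DataFrame(rows)


def simulate_battery(
    cohort: list[RespondentProfile], seed: int = 0, loading: float = 0.6
) -> pd.DataFrame:
    """Synthetic laboratory battery standard scores (mean 100, SD 15).

    Each column loads on the participant's mean latent ability with the
    given loading, emulating age-corrected standard scores from a
    criterion battery for convergent-validity analyses.
    """
    rng = np.random.default_rng(seed)
    cols = ["fluid_cognition", "flanker", "card_sort", "pattern_comparison",
            "list_sorting", "picture_sequence", "dkefs_color_word"]
    rows = []
    for p in cohort:
        a = float(np.mean(list(p.ability.values())))
        row = {"participant_id": p.participant_id}
        for c in cols:
            noise = rng.normal(0.0, math.sqrt(1 - loading ** 2))
            row[c] = 100.0 + 15.0 * (loading * a + noise)
        rows.append(row)
    return pd.DataFrame(rows)
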