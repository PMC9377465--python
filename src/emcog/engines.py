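"""Deterministic engines for the seven mobile cognitive tests.

Each engine is a state machine: it generates stimuli from a seeded RNG,
hands them to a *responder*, adjudicates the response, applies the
test's scoring rule, and terminates by its own rule (fixed time, error
limit, or trial count).  A responder is any callable

    responder(stimulus: dict) -> (response: dict | None, latency_s: float)

For the Quick Tap tests the response itself carries the tap latency and
the returned latency is ignored (the engine derives trial timing from
the onset and the tap).

Scoring rules
-------------
* Matching Pair — running weighted-accuracy score: a correct selection
  adds the current grid's tile count (rows x cols); errors leave the
  score unchanged.  The grid ladder starts at 2x2 and advances one step
  per correct trial up to 4x4.  Fixed 90 s session.
* Memory Matrix — adaptive span: a correct reproduction adds the span
  to the score and grows the span by 1 (cap 11); an error shrinks it by
  1 (floor 1).  The session ends at 3 cumulative errors.
* Odd One Out — 9 trials of 6 symbols (5 identical + 1 odd); score is
  the number correct; mean reaction time is the secondary outcome.
* VLMT — 12-word study list; 24-item yes/no recognition (12 targets +
  12 foils); score = hits + correct rejections, max 24.
* Quick Tap 1 — 12 trials; target onset uniform in 1-5 s; score is the
  mean reaction time over correct trials (taps within 2 s of onset).
* Quick Tap 2 — go/no-go variant: foils appear with a per-trial
  probability drawn from 30-60%; one point per correct go (tap) or
  correct withhold; max 12.
* CopyKat — Simon-style sequence reproduction over 4 tiles; correct
  trials extend the sequence by one tile, errors re-present the same
  sequence; the session ends at 3 errors; score = correct trials.

All stimulus randomness flows from the per-session ``seed``; simulated
responder behaviour should use its own independent RNG so stimuli and
behaviour are separately reproducible.  Responses landing exactly on a
timeout boundary (2 s, 20 s) count as in time.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .config import EngineConfig
from .types import (
    InvalidStimulusError,
    OrderingError,
    ProtocolError,
    SessionResult,
    TrialEvent,
    mean_or_nan,
)

Responder = Callable[[dict], tuple[Optional[dict], float]]


# ---------------------------------------------------------------------------
# score-update primitives
# ---------------------------------------------------------------------------

def matching_pair_update(prev_score: float, grid: tuple[int, int], correct: bool) -> float:
    """Running-score update for Matching Pair.

    A correct trial adds the tile count of the grid shown (e.g. a 3x3
    grid adds 9); an incorrect trial leaves the score unchanged.
    """
    rows, cols = grid
    if rows <= 0 or cols <= 0:
        raise InvalidStimulusError(f"non-positive grid dims {grid}")
    if prev_score < 0:
        raise ValueError("running score cannot be negative")
    return prev_score + rows * cols if correct else prev_score


def memory_matrix_update(
    prev_score: float,
    span: int,
    correct: bool,
    span_min: int = 1,
    span_max: int = 11,
) -> tuple[float, int]:
    """Running-score and span update for Memory Matrix.

    Correct: the span is added to the score and the next span grows by
    one (capped at ``span_max``).  Incorrect: the score is unchanged and
    the span shrinks by one (floored at ``span_min``).
    """
    if not (span_min <= span <= span_max):
        raise InvalidStimulusError(f"span {span} outside [{span_min}, {span_max}]")
    if correct:
        return prev_score + span, min(span + 1, span_max)
    return prev_score, max(span - 1, span_min)


def score_vlmt(responses: Sequence[bool], truth: Sequence[bool]) -> int:
    """Recognition score: hits plus correct rejections (max 24).

    ``truth[i]`` is True for targets; ``responses[i]`` is the yes/no
    answer.  Requires 24 items with exactly 12 targets and 12 foils.
    """
    if len(responses) != 24 or len(truth) != 24:
        raise ValueError("recognition phase has exactly 24 items")
    n_targets = sum(bool(t) for t in truth)
    if n_targets != 12:
        raise ValueError("truth labels must contain 12 targets and 12 foils")
    return sum(bool(r) == bool(t) for r, t in zip(responses, truth))


def memory_matrix_grid_side(span: int, grid_max: tuple[int, int] = (7, 7)) -> int:
    """Grid side for a given span: smallest g with g*g >= 2*span, capped.

    Keeps highlighted-tile density at or below 50% while honouring the
    2x2..7x7 grid bounds.
    """
    g = max(2, math.ceil(math.sqrt(2 * span)))
    return min(g, grid_max[0], grid_max[1])


# ---------------------------------------------------------------------------
# adjudication (stimulus + response -> correct), shared by engines & re-scoring
# ---------------------------------------------------------------------------

def adjudicate(test_id: str, stimulus: dict, response: Optional[dict]) -> bool:
    """Re-derive the correctness flag from a stored stimulus/response pair."""
    if test_id == "matching_pair":
        if response is None:
            return False
        i, j = response["selected"]
        colors = stimulus["colors"]
        n = len(colors)
        if not (0 <= i < n and 0 <= j < n) or i == j:
            return False
        return colors[i] == colors[j]

    if test_id == "memory_matrix":
        if response is None:
            return False
        side = stimulus["side"]
        sel = response["selected"]
        if any(not (0 <= t < side * side) for t in sel):
            return False  # off-grid taps adjudicated incorrect, not an error
        return set(sel) == set(stimulus["targets"])

    if test_id == "odd_one_out":
        if response is None:
            return False
        symbols = stimulus["symbols"]
        idx = response["selected"]
        if not (0 <= idx < len(symbols)):
            return False
        return symbols.count(symbols[idx]) == 1

    if test_id == "vlmt":
        if stimulus.get("phase") == "study":
            return True  # study exposure has no right/wrong answer
        if response is None or response.get("yes") is None:
            return False
        return bool(response["yes"]) == bool(stimulus["is_target"])

    if test_id == "quick_tap1":
        lat = None if response is None else response.get("tap_latency_s")
        timeout = stimulus.get("timeout_s", 2.0)
        return lat is not None and 0.0 < lat <= timeout

    if test_id == "quick_tap2":
        lat = None if response is None else response.get("tap_latency_s")
        timeout = stimulus.get("timeout_s", 2.0)
        tapped_in_time = lat is not None and 0.0 < lat <= timeout
        if stimulus["is_foil"]:
            # withholding means no tap at any point while the foil shows
            return lat is None or lat > timeout
        return tapped_in_time

    if test_id == "copykat":
        if response is None or response.get("sequence") is None:
            return False
        if response.get("elapsed_s", 0.0) > stimulus.get("timeout_s", 20.0):
            return False
        return list(response["sequence"]) == list(stimulus["sequence"])

    raise ValueError(f"unknown test_id {test_id!r}")


# ---------------------------------------------------------------------------
# engines
# ---------------------------------------------------------------------------

def run_matching_pair(
    responder: Responder, config: EngineConfig | None = None, seed: int = 0
) -> SessionResult:
    """Fixed-time (90 s) colour-matching session.

    Exactly one pair of tiles shares a colour; the grid advances one
    step along the configured ladder after each correct trial and never
    shrinks.  The session stops once cumulative trial time reaches the
    time limit.
    """
    config = config or EngineConfig()
    rng = np.random.default_rng(seed)
    seq = config.matching_pair_grid_sequence
    grid_idx = 0
    score = 0.0
    elapsed = 0.0
    trials: list[TrialEvent] = []

    while elapsed < config.matching_pair_duration_s:
        rows, cols = seq[grid_idx]
        n = rows * cols
        colors = list(range(n))
        i, j = (int(x) for x in rng.choice(n, size=2, replace=False))
        colors[j] = colors[i]  # exactly one matching pair
        stimulus = {"rows": rows, "cols": cols, "colors": colors}
        response, latency = responder(stimulus)
        if latency is None or latency < 0:
            raise ProtocolError("responder returned invalid latency")
        correct = adjudicate("matching_pair", stimulus, response)
        trials.append(
            TrialEvent("matching_pair", len(trials), stimulus, response,
                       float(latency), correct, elapsed)
        )
        score = matching_pair_update(score, (rows, cols), correct)
        if correct:
            grid_idx = min(grid_idx + 1, len(seq) - 1)
        elapsed += latency

    return _result("matching_pair", score, trials, "time_limit",
                   rt_trials=lambda t: t.correct)


def run_memory_matrix(
    responder: Responder, config: EngineConfig | None = None, seed: int = 0
) -> SessionResult:
    """Adaptive-span tile-pattern session; ends at 3 cumulative errors."""
    config = config or EngineConfig()
    rng = np.random.default_rng(seed)
    span = config.memory_matrix_span_min
    score = 0.0
    errors = 0
    elapsed = 0.0
    trials: list[TrialEvent] = []
    terminated_by = "error_limit"

    while errors < config.memory_matrix_error_limit:
        if len(trials) >= config.memory_matrix_max_trials:
            terminated_by = "trial_count"
            break
        side = memory_matrix_grid_side(span, config.memory_matrix_grid_max)
        targets = sorted(int(t) for t in rng.choice(side * side, size=span, replace=False))
        stimulus = {"side": side, "targets": targets,
                    "presentation_s": config.memory_matrix_presentation_s}
        response, latency = responder(stimulus)
        if latency is None or latency < 0:
            raise ProtocolError("responder returned invalid latency")
        correct = adjudicate("memory_matrix", stimulus, response)
        trials.append(
            TrialEvent("memory_matrix", len(trials), stimulus, response,
                       float(latency), correct, elapsed)
        )
        score, span = memory_matrix_update(
            score, span, correct,
            config.memory_matrix_span_min, config.memory_matrix_span_max,
        )
        if not correct:
            errors += 1
        elapsed += config.memory_matrix_presentation_s + latency

    return _result("memory_matrix", score, trials, terminated_by,
                   rt_trials=lambda t: t.correct)


def run_odd_one_out(
    responder: Responder, config: EngineConfig | None = None, seed: int = 0
) -> SessionResult:
    """Nine trials of 5-identical-plus-1-odd symbol search."""
    config = config or EngineConfig()
    rng = np.random.default_rng(seed)
    k = config.odd_one_out_symbols_per_trial
    trials: list[TrialEvent] = []
    elapsed = 0.0

    for _ in range(config.odd_one_out_trials):
        common, odd = (int(s) for s in rng.choice(config.odd_one_out_symbol_pool,
                                                  size=2, replace=False))
        symbols = [common] * k
        symbols[int(rng.integers(k))] = odd
        stimulus = {"symbols": symbols}
        response, latency = responder(stimulus)
        if latency is None or latency < 0:
            raise ProtocolError("responder returned invalid latency")
        correct = adjudicate("odd_one_out", stimulus, response)
        trials.append(
            TrialEvent("odd_one_out", len(trials), stimulus, response,
                       float(latency), correct, elapsed)
        )
        elapsed += latency

    # reaction time over all trials is the secondary (processing speed) outcome
    return _result("odd_one_out", float(sum(t.correct for t in trials)),
                   trials, "trial_count", rt_trials=lambda t: True)


def vlmt_word_list(list_id: int, config: EngineConfig | None = None) -> tuple[list[str], list[str]]:
    """Deterministic alternate-form word list: (targets, foils) for a list id.

    Lists are synthetic pronounceable tokens generated from the list id
    alone, so study and recognition phases agree on the materials
    without shared state.
    """
    config = config or EngineConfig()
    rng = np.random.default_rng(977_131 + 7 * int(list_id))
    consonants = "bdfgklmnprstvz"
    vowels = "aeiou"
    words: list[str] = []
    seen = set()
    while len(words) < 2 * config.vlmt_list_length:
        w = "".join(
            consonants[rng.integers(len(consonants))] + vowels[rng.integers(len(vowels))]
            for _ in range(2)
        )
        if w not in seen:
            seen.add(w)
            words.append(w)
    n = config.vlmt_list_length
    return words[:n], words[n:]


def run_vlmt(
    list_id: int,
    phase: str,
    responder: Responder,
    config: EngineConfig | None = None,
    seed: int = 0,
    studied_lists: Optional[Iterable[int]] = None,
) -> SessionResult:
    """List-memory phase runner.

    ``phase`` is ``study`` (30 s exposure of the 12 targets, unscored),
    ``short_delay`` or ``long_delay`` (24-item yes/no recognition).  If
    ``studied_lists`` is given, recognition of an unstudied list raises
    :class:`OrderingError`.
    """
    config = config or EngineConfig()
    if phase not in ("study", "short_delay", "long_delay"):
        raise ValueError(f"unknown phase {phase!r}")
    targets, foils = vlmt_word_list(list_id, config)

    if phase == "study":
        stimulus = {"phase": "study", "words": list(targets),
                    "study_s": config.vlmt_study_s}
        responder(stimulus)  # exposure only; nothing to adjudicate
        ev = TrialEvent("vlmt", 0, stimulus, None, config.vlmt_study_s, True, 0.0)
        return SessionResult("vlmt", float("nan"), None, 1, 1, 0, "trial_count", [ev])

    if studied_lists is not None and list_id not in set(studied_lists):
        raise OrderingError(f"recognition of list {list_id} before study")

    rng = np.random.default_rng(seed)
    items = [(w, True) for w in targets] + [(w, False) for w in foils]
    order = rng.permutation(len(items))
    trials: list[TrialEvent] = []
    elapsed = 0.0
    for idx in order:
        word, is_target = items[int(idx)]
        stimulus = {"phase": phase, "word": word, "is_target": is_target,
                    "list_id": int(list_id)}
        response, latency = responder(stimulus)
        if latency is None or latency < 0:
            raise ProtocolError("responder returned invalid latency")
        correct = adjudicate("vlmt", stimulus, response)
        trials.append(TrialEvent("vlmt", len(trials), stimulus, response,
                                 float(latency), correct, elapsed))
        elapsed += latency

    score = float(sum(t.correct for t in trials))
    return _result("vlmt", score, trials, "trial_count", rt_trials=lambda t: True)


def run_quick_tap1(
    responder: Responder, config: EngineConfig | None = None, seed: int = 0
) -> SessionResult:
    """Simple reaction-time session: 12 trials, score = mean correct RT.

    The response dict carries ``tap_latency_s`` relative to target
    onset: a value in (0, 2] is a correct tap, a non-positive value is a
    premature tap, None means no tap (timeout).  With zero correct
    trials the score is NaN (flagged missing, not an error).
    """
    return _run_quick_tap(responder, config, seed, with_foils=False)


def run_quick_tap2(
    responder: Responder, config: EngineConfig | None = None, seed: int = 0
) -> SessionResult:
    """Go/no-go session: tap targets, withhold on foils; score = n correct."""
    return _run_quick_tap(responder, config, seed, with_foils=True)


def _run_quick_tap(responder, config, seed, with_foils: bool) -> SessionResult:
    config = config or EngineConfig()
    rng = np.random.default_rng(seed)
    lo, hi = config.quick_tap_wait_interval_s
    timeout = config.quick_tap_response_timeout_s
    test_id = "quick_tap2" if with_foils else "quick_tap1"
    trials: list[TrialEvent] = []
    elapsed = 0.0

    for _ in range(config.quick_tap_trials):
        onset = float(rng.uniform(lo, hi))
        stimulus = {"onset_s": onset, "timeout_s": timeout}
        if with_foils:
            plo, phi = config.quick_tap2_foil_prob_range
            foil_p = float(rng.uniform(plo, phi))
            stimulus["foil_prob"] = foil_p
            stimulus["is_foil"] = bool(rng.random() < foil_p)
        response, _ = responder(stimulus)
        lat = None if response is None else response.get("tap_latency_s")
        correct = adjudicate(test_id, stimulus, response)
        # trial clock time: premature taps end the trial at the tap
        if lat is None:
            trial_time = onset + timeout
        elif lat <= 0:
            trial_time = max(onset + lat, 0.0)
        else:
            trial_time = onset + min(lat, timeout)
        trials.append(TrialEvent(test_id, len(trials), stimulus, response,
                                 trial_time, correct, elapsed))
        elapsed += trial_time

    def _tapped_target(t: TrialEvent) -> bool:
        lat = None if t.response is None else t.response.get("tap_latency_s")
        on_target = not t.stimulus.get("is_foil", False)
        return t.correct and on_target and lat is not None

    rts = [t.response["tap_latency_s"] for t in trials if _tapped_target(t)]
    rt_mean = mean_or_nan(rts)
    if with_foils:
        score = float(sum(t.correct for t in trials))
    else:
        score = rt_mean
    return SessionResult(
        test_id, score, None if math.isnan(rt_mean) else rt_mean,
        len(trials), sum(t.correct for t in trials),
        sum(not t.correct for t in trials), "trial_count", trials,
    )


def run_copykat(
    responder: Responder, config: EngineConfig | None = None, seed: int = 0
) -> SessionResult:
    """Sequence-reproduction session over 4 fixed tiles.

    The sequence starts at length 1; each correct reproduction appends
    one tile, each error re-presents the identical sequence.  The
    response dict carries ``sequence`` (ordered tile ids, or None for no
    response) and ``elapsed_s``; responses beyond 20 s are incorrect.
    Score = number of correct trials, no upper limit.
    """
    config = config or EngineConfig()
    rng = np.random.default_rng(seed)
    sequence = [int(rng.integers(config.copykat_n_tiles))]
    errors = 0
    elapsed = 0.0
    trials: list[TrialEvent] = []
    terminated_by = "error_limit"

    while errors < config.copykat_error_limit:
        if len(trials) >= config.copykat_max_trials:
            terminated_by = "trial_count"
            break
        stimulus = {"sequence": list(sequence),
                    "timeout_s": config.copykat_response_timeout_s}
        response, latency = responder(stimulus)
        if latency is None or latency < 0:
            raise ProtocolError("responder returned invalid latency")
        if response is not None and "elapsed_s" not in response:
            response = dict(response, elapsed_s=float(latency))
        correct = adjudicate("copykat", stimulus, response)
        trials.append(TrialEvent("copykat", len(trials), stimulus, response,
                                 float(latency), correct, elapsed))
        if correct:
            sequence.append(int(rng.integers(config.copykat_n_tiles)))
        else:
            errors += 1
        elapsed += latency

    score = float(sum(t.correct for t in trials))
    # mean per-step response time over correct trials (secondary outcome)
    step_rts = [
        t.latency_s / len(t.stimulus["sequence"]) for t in trials if t.correct
    ]
    res = _result("copykat", score, trials, terminated_by, rt_trials=lambda t: False)
    res.rt_mean_s = mean_or_nan(step_rts) if step_rts else None
    return res


RUNNERS = {
    "matching_pair": run_matching_pair,
    "memory_matrix": run_memory_matrix,
    "odd_one_out": run_odd_one_out,
    "quick_tap1": run_quick_tap1,
    "quick_tap2": run_quick_tap2,
    "copykat": run_copykat,
}


# ---------------------------------------------------------------------------
# re-scoring from stored trial logs
# ---------------------------------------------------------------------------

def rescore_session(test_id: str, trials: list[TrialEvent]) -> float:
    """Recompute the primary score from raw trial records.

    Re-adjudicates every trial from its stimulus and response and folds
    the test's scoring rule over the results; used to verify the
    log -> score round trip and to score user-supplied logs.
    """
    flags = [adjudicate(test_id, t.stimulus, t.response) for t in trials]

    if test_id == "matching_pair":
        score = 0.0
        for t, ok in zip(trials, flags):
            score = matching_pair_update(
                score, (t.stimulus["rows"], t.stimulus["cols"]), ok)
        return score
    if test_id == "memory_matrix":
        score = 0.0
        for t, ok in zip(trials, flags):
            span = len(t.stimulus["targets"])
            if ok:
                score += span
        return score
    if test_id in ("odd_one_out", "quick_tap2", "copykat"):
        return float(sum(flags))
    if test_id == "vlmt":
        if trials and trials[0].stimulus.get("phase") == "study":
            return float("nan")
        return float(sum(flags))
    if test_id == "quick_tap1":
        rts = [
            t.response["tap_latency_s"]
            for t, ok in zip(trials, flags)
            if ok and t.response is not None
        ]
        return mean_or_nan(rts)
    raise ValueError(f"unknown test_id {test_id!r}")


def session_rt(test_id: str, trials: list[TrialEvent]) -> float:
    """Secondary reaction-time summary recomputed from trial records.

    Mirrors each engine's convention: correct-trial latency for the
    matching and span tests, all-trial latency for symbol search and
    recognition, tap latency on correct target trials for the Quick
    Taps, and per-step time on correct trials for the sequence test.
    """
    if test_id in ("matching_pair", "memory_matrix"):
        return mean_or_nan([t.latency_s for t in trials if t.correct])
    if test_id in ("odd_one_out", "vlmt"):
        if trials and trials[0].stimulus.get("phase") == "study":
            return float("nan")
        return mean_or_nan([t.latency_s for t in trials])
    if test_id in ("quick_tap1", "quick_tap2"):
        rts = []
        for t in trials:
            lat = None if t.response is None else t.response.get("tap_latency_s")
            if t.correct and lat is not None and not t.stimulus.get("is_foil", False):
                rts.append(lat)
        return mean_or_nan(rts)
    if test_id == "copykat":
        return mean_or_nan([t.latency_s / len(t.stimulus["sequence"])
                            for t in trials if t.correct])
    raise ValueError(f"unknown test_id {test_id!r}")


def _result(test_id, score, trials, terminated_by, rt_trials) -> SessionResult:
    rts = [t.latency_s for t in trials if rt_trials(t)]
    rt_mean = mean_or_nan(rts)
    return SessionResult(
        test_id=test_id,
        score=float(score),
        rt_mean_s=None if math.isnan(rt_mean) else rt_mean,
        n_trials=len(trials),
        n_correct=sum(t.correct for t in trials),
        n_incorrect=sum(not t.correct for t in trials),
        terminated_by=terminated_by,
        trials=trials,
    )
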