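"""14-day ambulatory testing protocol: schedule construction & validation.

Each participant receives 3 notifications per day (morning MA, midday
MD, early-evening EE) for 14 days — 42 sessions.  Notification times
are placed inside the participant's wake span with a 2-hour minimum
between sessions, and each link expires 60 minutes after notification.
Test-to-session assignment follows a counterbalanced table under which
every test is administered 9 times over the 14 days, except the
list-memory (VLMT) study+short-delay recognition, which runs daily; on
8 of the days a long-delay recognition of the same day's list occurs in
a later session, with the intervening tests acting as the distractor.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

WINDOWS = ("MA", "MD", "EE")
N_DAYS = 14

#: Phase markers used inside session test lists.
VLMT_STUDY = "vlmt_study"
VLMT_SHORT = "vlmt_recog_short"
VLMT_LONG = "vlmt_recog_long"

# Default counterbalanced day->window assignment for each test (the
# administration grid of the 14-day protocol).  Non-VLMT tests appear on
# 9 days; the VLMT study list is presented daily, and on dual-window
# days the recognition phase repeats later the same day (long delay).
DEFAULT_ASSIGNMENT: dict[str, dict[int, list[str]]] = {
    "matching_pair": {1: ["MA"], 2: ["EE"], 3: ["EE"], 4: ["EE"], 5: ["MA"],
                      9: ["MD"], 12: ["MA"], 13: ["MD"], 14: ["MD"]},
    "memory_matrix": {2: ["MD"], 4: ["MA"], 5: ["MD"], 6: ["MA"], 7: ["EE"],
                      9: ["EE"], 10: ["EE"], 12: ["EE"], 14: ["MA"]},
    "odd_one_out": {2: ["MA"], 4: ["MD"], 5: ["EE"], 8: ["EE"], 9: ["MA"],
                    10: ["MA"], 11: ["MD"], 12: ["MA"], 14: ["EE"]},
    "vlmt_recall": {1: ["EE"], 2: ["MA"], 3: ["MA"], 4: ["EE"], 5: ["MA"],
                    6: ["MD"], 7: ["MD"], 8: ["MD"], 9: ["EE"], 10: ["MA"],
                    11: ["EE"], 12: ["MD"], 13: ["MD"], 14: ["EE"]},
    "vlmt_recognition": {1: ["EE"], 2: ["MA", "MD"], 3: ["MA", "MD"],
                         4: ["EE"], 5: ["MA", "MD"], 6: ["MD", "EE"],
                         7: ["MD"], 8: ["MD", "EE"], 9: ["EE"],
                         10: ["MA", "MD"], 11: ["EE"], 12: ["MD", "EE"],
                         13: ["MD", "EE"], 14: ["EE"]},
    "quick_tap1": {1: ["EE"], 3: ["MA"], 6: ["MD"], 7: ["MD"], 8: ["MD"],
                   10: ["EE"], 11: ["MA"], 12: ["MD"], 14: ["MA"]},
    "quick_tap2": {1: ["EE"], 3: ["MA"], 6: ["MD"], 7: ["MD"], 8: ["MD"],
                   10: ["EE"], 11: ["MA"], 12: ["MD"], 14: ["MA"]},
    "copykat": {1: ["MD"], 3: ["MD"], 6: ["EE"], 7: ["MA"], 8: ["MA"],
                9: ["MD"], 11: ["EE"], 12: ["EE"], 13: ["MA"]},
}

MIN_GAP_MIN = 120      # 2-hour minimum between sessions
EXPIRY_MIN = 60        # links active for 1 hour
MIN_WAKE_SPAN_MIN = 8 * 60


class SchedulingError(ValueError):
    pass


def _to_minutes(clock: str) -> int:
    h, m = clock.split(":")
    return int(h) * 60 + int(m)


def _to_clock(minutes: int) -> str:
    return f"{minutes // 60 % 24:02d}:{minutes % 60:02d}"


@dataclass
class ScheduleEntry:
    participant_id: str
    day: int                 # 1..14
    window: str              # MA / MD / EE
    notify_min: int          # minutes since midnight
    tests: list[str] = field(default_factory=list)

    @property
    def expiry_min(self) -> int:
        return self.notify_min + EXPIRY_MIN

    @property
    def notify_time(self) -> str:
        return _to_clock(self.notify_min)

    @property
    def expiry_time(self) -> str:
        return _to_clock(self.expiry_min)


@dataclass
class ProtocolSchedule:
    participant_id: str
    entries: list[ScheduleEntry]

    def sessions_on(self, day: int) -> list[ScheduleEntry]:
        return sorted((e for e in self.entries if e.day == day),
                      key=lambda e: e.notify_min)

    def administration_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            for t in e.tests:
                counts[t] = counts.get(t, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.entries)


def _session_test_order(items: list[str]) -> list[str]:
    """Order tests within a session.

    The VLMT study list comes first and its short-delay recognition
    last, so the other tests of the session serve as the distractor
    task; the inhibition Quick Tap always immediately follows the simple
    Quick Tap; a long-delay recognition (of the morning's list) runs
    before the day's new study phase would interfere — it is placed
    right after any study phase, ahead of the distractors.
    """
    canon = ["matching_pair", "memory_matrix", "odd_one_out",
             "quick_tap1", "quick_tap2", "copykat"]
    middle = [t for t in canon if t in items]
    out: list[str] = []
    if VLMT_STUDY in items:
        out.append(VLMT_STUDY)
    if VLMT_LONG in items:
        out.append(VLMT_LONG)
    out.extend(middle)
    if VLMT_SHORT in items:
        out.append(VLMT_SHORT)
    return out


def build_schedule(
    participant_id: str,
    wake_time: str = "08:00",
    sleep_time: str = "22:00",
    assignment_table: Optional[dict] = None,
    seed: int = 0,
) -> ProtocolSchedule:
    """Build one participant's 42-session protocol schedule.

    The wake span is split into three equal tertiles; a notification
    time is drawn uniformly inside each (seeded), then repaired forward
    so consecutive sessions sit at least 2 hours apart.  Test
    assignments come from ``assignment_table`` (default: the
    counterbalanced grid above).
    """
    table = assignment_table or DEFAULT_ASSIGNMENT
    _validate_assignment(table)
    wake, sleep = _to_minutes(wake_time), _to_minutes(sleep_time)
    if sleep <= wake:
        sleep += 24 * 60  # sleep past midnight
    span = sleep - wake
    if span < MIN_WAKE_SPAN_MIN:
        raise SchedulingError(
            f"wake span {span} min < {MIN_WAKE_SPAN_MIN} min; "
            "2-hour session spacing may be infeasible")

    rng = np.random.default_rng(seed)
    entries: list[ScheduleEntry] = []
    tertile = span / 3.0
    for day in range(1, N_DAYS + 1):
        times = []
        for k in range(3):
            lo = wake + k * tertile
            hi = wake + (k + 1) * tertile - EXPIRY_MIN  # leave room for the link
            times.append(int(rng.uniform(lo, max(lo + 1, hi))))
        # forward repair of the 2 h spacing constraint
        for k in (1, 2):
            times[k] = max(times[k], times[k - 1] + MIN_GAP_MIN)
        for window, notify in zip(WINDOWS, times):
            entries.append(ScheduleEntry(participant_id, day, window, notify,
                                         _tests_for(table, day, window)))
    return ProtocolSchedule(participant_id, entries)


def _tests_for(table: dict, day: int, window: str) -> list[str]:
    items: list[str] = []
    recall_win = table["vlmt_recall"].get(day, [None])[0]
    recog_wins = table["vlmt_recognition"].get(day, [])
    if window == recall_win:
        items.append(VLMT_STUDY)
        if window in recog_wins:
            items.append(VLMT_SHORT)
    elif window in recog_wins:
        items.append(VLMT_LONG)
    for test in ("matching_pair", "memory_matrix", "odd_one_out",
                 "quick_tap1", "quick_tap2", "copykat"):
        if window in table[test].get(day, []):
            items.append(test)
    return _session_test_order(items)


def _validate_assignment(table: dict) -> None:
    for test in ("matching_pair", "memory_matrix", "odd_one_out",
                 "quick_tap1", "quick_tap2", "copykat"):
        n = sum(len(v) for v in table.get(test, {}).values())
        if n != 9:
            raise SchedulingError(
                f"assignment table gives {test} {n} administrations, expected 9")
    if set(table.get("vlmt_recall", {})) != set(range(1, N_DAYS + 1)):
        raise SchedulingError("list study must be scheduled every day")
    for day, wins in table.get("vlmt_recognition", {}).items():
        recall = table["vlmt_recall"].get(day, [None])[0]
        if recall not in wins:
            raise SchedulingError(
                f"day {day}: recognition windows {wins} must include the "
                f"study window {recall} (short delay)")


def validate_schedule(schedule: ProtocolSchedule) -> list[str]:
    """Return a list of human-readable protocol violations (empty = valid)."""
    v: list[str] = []
    if len(schedule.entries) != N_DAYS * 3:
        v.append(f"expected {N_DAYS * 3} sessions, found {len(schedule.entries)}")

    for day in range(1, N_DAYS + 1):
        sessions = schedule.sessions_on(day)
        for a, b in zip(sessions, sessions[1:]):
            gap = b.notify_min - a.notify_min
            if gap < MIN_GAP_MIN:
                v.append(f"day {day}: sessions {a.window}->{b.window} only "
                         f"{gap} min apart (< {MIN_GAP_MIN})")
        # once-per-day rule for the non-VLMT tests
        seen: dict[str, int] = {}
        for e in sessions:
            for t in e.tests:
                if t in ("matching_pair", "memory_matrix", "odd_one_out",
                         "quick_tap1", "quick_tap2", "copykat"):
                    seen[t] = seen.get(t, 0) + 1
        for t, n in seen.items():
            if n > 1:
                v.append(f"day {day}: {t} administered {n} times (max once/day)")
        # daily list study; long delay must follow the study session
        phases = [(e.notify_min, t) for e in sessions for t in e.tests
                  if t.startswith("vlmt")]
        if not any(t == VLMT_STUDY for _, t in phases):
            v.append(f"day {day}: no list study phase scheduled")
        study_times = [m for m, t in phases if t == VLMT_STUDY]
        for m, t in phases:
            if t == VLMT_LONG and study_times and m <= min(study_times):
                v.append(f"day {day}: long-delay recognition not in a later "
                         "session than the study phase")
        # the inhibition tap task immediately follows the simple tap task
        for e in sessions:
            if "quick_tap2" in e.tests:
                i = e.tests.index("quick_tap2")
                if i == 0 or e.tests[i - 1] != "quick_tap1":
                    v.append(f"day {day} {e.window}: quick_tap2 not "
                             "immediately after quick_tap1")

    counts = schedule.administration_counts()
    for t in ("matching_pair", "memory_matrix", "odd_one_out",
              "quick_tap1", "quick_tap2", "copykat"):
        if counts.get(t, 0) != 9:
            v.append(f"{t}: {counts.get(t, 0)} administrations, expected 9")
    if counts.get(VLMT_STUDY, 0) != N_DAYS:
        v.append(f"list study: {counts.get(VLMT_STUDY, 0)} administrations, "
                 f"expected {N_DAYS}")
    return v


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def schedule_to_csv(schedule: ProtocolSchedule, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["participant_id", "day", "window", "notify_time",
                    "expiry_time", "tests"])
        for e in schedule.entries:
            w.writerow([e.participant_id, e.day, e.window, e.notify_time,
                        e.expiry_time, "|".join(e.tests)])


def schedule_from_csv(path: str | Path) -> ProtocolSchedule:
    entries: list[ScheduleEntry] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append(ScheduleEntry(
                participant_id=row["participant_id"],
                day=int(row["day"]),
                window=row["window"],
                notify_min=_to_minutes(row["notify_time"]),
                tests=[t for t in row["tests"].split("|") if t],
            ))
    pid = entries[0].participant_id if entries else ""
    return ProtocolSchedule(pid, entries)
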