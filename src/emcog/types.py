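"""Core domain types shared across the package.

A *trial* is one stimulus/response exchange inside a mobile cognitive
test; a *session result* is the scored outcome of one administration of
one test.  Both are plain dataclasses with JSON-friendly converters so
trial logs can round-trip through JSONL files and be re-scored from the
raw records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any, Optional

TEST_IDS = (
    "matching_pair",
    "memory_matrix",
    "odd_one_out",
    "vlmt",
    "quick_tap1",
    "quick_tap2",
    "copykat",
)

#: Termination reasons a session can report.
TERMINATIONS = ("time_limit", "error_limit", "trial_count")


class InvalidStimulusError(ValueError):
    """A stimulus descriptor violates the engine's constraints."""


class ProtocolError(ValueError):
    """A responder broke its contract (e.g. negative latency)."""


class OrderingError(ValueError):
    """A recognition phase was requested before its study phase."""


@dataclass
class TrialEvent:
    """One stimulus/response exchange inside a test session."""

    test_id: str
    trial_index: int
    stimulus: dict
    response: Optional[dict]
    latency_s: float
    correct: bool
    timestamp: float  # seconds since session start

    def __post_init__(self) -> None:
        if self.test_id not in TEST_IDS:
            raise ValueError(f"unknown test_id {self.test_id!r}")
        if self.latency_s < 0:
            raise ProtocolError(f"negative latency {self.latency_s}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrialEvent":
        return cls(
            test_id=d["test_id"],
            trial_index=int(d["trial_index"]),
            stimulus=d["stimulus"],
            response=d["response"],
            latency_s=float(d["latency_s"]),
            correct=bool(d["correct"]),
            timestamp=float(d["timestamp"]),
        )


@dataclass
class SessionResult:
    """Scored outcome of one administration of one test.

    ``score`` is the test's primary outcome (running weighted score,
    total correct, or mean reaction time depending on the test) and is
    NaN when undefined (e.g. Quick Tap 1 with zero correct trials, or a
    study-only phase).  ``rt_mean_s`` is the secondary reaction-time
    summary where the test defines one.
    """

    test_id: str
    score: float
    rt_mean_s: Optional[float]
    n_trials: int
    n_correct: int
    n_incorrect: int
    terminated_by: str
    trials: list[TrialEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.terminated_by not in TERMINATIONS:
            raise ValueError(f"unknown termination {self.terminated_by!r}")
        if self.n_correct + self.n_incorrect != self.n_trials:
            raise ValueError("n_correct + n_incorrect must equal n_trials")

    @property
    def score_missing(self) -> bool:
        return self.score is None or (
            isinstance(self.score, float) and math.isnan(self.score)
        )


def mean_or_nan(values: list[float]) -> float:
    return float(sum(values) / len(values)) if values else float("nan")
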