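"""Engine configuration.

All timing, grid, and trial-count parameters of the seven mobile tests
live here with the platform defaults: Matching Pair runs for a fixed 90
seconds over a 2x2..4x4 grid ladder; Memory Matrix presents the pattern
for 1.5 s, adapts the span between 1 and 11 highlighted tiles on a grid
of at most 7x7, and stops at 3 errors; Odd One Out has 9 six-symbol
trials; the list-memory test uses 12-word lists with a 24-item
recognition phase; both Quick Tap variants run 12 trials with a 1-5 s
onset window and a 2 s response timeout, the inhibition variant drawing
its foil probability from 30-60%; CopyKat stops at 3 errors with a 20 s
per-trial timeout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class EngineConfig:
    matching_pair_duration_s: float = 90.0
    matching_pair_grid_sequence: tuple = ((2, 2), (2, 3), (3, 3), (3, 4), (4, 4))

    memory_matrix_presentation_s: float = 1.5
    memory_matrix_span_min: int = 1
    memory_matrix_span_max: int = 11
    memory_matrix_error_limit: int = 3
    memory_matrix_grid_max: tuple = (7, 7)
    memory_matrix_max_trials: int = 100  # guard: a perfect run never errors out

    odd_one_out_trials: int = 9
    odd_one_out_symbols_per_trial: int = 6
    odd_one_out_symbol_pool: int = 20

    vlmt_list_length: int = 12
    vlmt_study_s: float = 30.0
    vlmt_recognition_items: int = 24

    quick_tap_trials: int = 12
    quick_tap_wait_interval_s: tuple = (1.0, 5.0)
    quick_tap_response_timeout_s: float = 2.0
    quick_tap2_foil_prob_range: tuple = (0.30, 0.60)

    copykat_error_limit: int = 3
    copykat_response_timeout_s: float = 20.0
    copykat_n_tiles: int = 4
    copykat_max_trials: int = 100

    def __post_init__(self) -> None:
        for name in (
            "matching_pair_duration_s",
            "memory_matrix_presentation_s",
            "vlmt_study_s",
            "quick_tap_response_timeout_s",
            "copykat_response_timeout_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.quick_tap2_foil_prob_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("foil probability range must lie within [0, 1]")
        rmax, cmax = self.memory_matrix_grid_max
        if self.memory_matrix_span_max > rmax * cmax:
            raise ValueError("span_max exceeds grid capacity")
        for r, c in self.matching_pair_grid_sequence:
            if r <= 0 or c <= 0:
                raise ValueError("grid dims must be positive")

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["matching_pair_grid_sequence"] = [list(g) for g in self.matching_pair_grid_sequence]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EngineConfig":
        d = dict(d)
        if "matching_pair_grid_sequence" in d:
            d["matching_pair_grid_sequence"] = tuple(
                tuple(g) for g in d["matching_pair_grid_sequence"]
            )
        for key in ("memory_matrix_grid_max", "quick_tap_wait_interval_s",
                    "quick_tap2_foil_prob_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "EngineConfig":
        """Load from a JSON or YAML document (by extension)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))
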