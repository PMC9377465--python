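"""Shared fixtures: scripted responders and a small simulated study."""

from __future__ import annotations

import numpy as np
import pytest

from emcog import CohortSpec, EngineConfig, sample_cohort, simulate_study
from emcog.simulate import simulate_battery


# ---------------------------------------------------------------------------
# scripted responders (ideal / degenerate behaviour)
# ---------------------------------------------------------------------------

def _find_pair(colors):
    return tuple(i for i in range(len(colors)) if colors.count(colors[i]) == 2)


def perfect_responder(test_id: str, latency: float = 1.0):
    """A responder that always answers correctly with fixed latency."""

    def respond(stim):
        if test_id == "matching_pair":
            return {"selected": _find_pair(stim["colors"])}, latency
        if test_id == "memory_matrix":
            return {"selected": list(stim["targets"])}, latency
        if test_id == "odd_one_out":
            sym = stim["symbols"]
            odd = next(i for i, s in enumerate(sym) if sym.count(s) == 1)
            return {"selected": odd}, latency
        if test_id == "vlmt":
            if stim.get("phase") == "study":
                return None, stim["study_s"]
            return {"yes": stim["is_target"]}, latency
        if test_id in ("quick_tap1", "quick_tap2"):
            if stim.get("is_foil"):
                return None, 0.0
            return {"tap_latency_s": 0.4}, 0.0
        if test_id == "copykat":
            return {"sequence": list(stim["sequence"]),
                    "elapsed_s": latency}, latency
        raise ValueError(test_id)

    return respond


def wrong_responder(test_id: str, latency: float = 1.0):
    """A responder that always answers incorrectly."""

    def respond(stim):
        if test_id == "matching_pair":
            pair = _find_pair(stim["colors"])
            other = next(i for i in range(len(stim["colors"])) if i not in pair)
            return {"selected": (pair[0], other)}, latency
        if test_id == "memory_matrix":
            return {"selected": []}, latency
        if test_id == "odd_one_out":
            sym = stim["symbols"]
            odd = next(i for i, s in enumerate(sym) if sym.count(s) == 1)
            return {"selected": (odd + 1) % len(sym)}, latency
        if test_id == "vlmt":
            if stim.get("phase") == "study":
                return None, stim["study_s"]
            return {"yes": not stim["is_target"]}, latency
        if test_id in ("quick_tap1", "quick_tap2"):
            if stim.get("is_foil"):
                return {"tap_latency_s": 0.5}, 0.0
            return None, 0.0
        if test_id == "copykat":
            bad = list(stim["sequence"]) + [0]
            return {"sequence": bad, "elapsed_s": latency}, latency
        raise ValueError(test_id)

    return respond


def noisy_responder(test_id: str, p_correct: float, seed: int):
    """Correct with probability p_correct, else wrong; seeded."""
    rng = np.random.default_rng(seed)
    good = perfect_responder(test_id, latency=1.0)
    bad = wrong_responder(test_id, latency=1.0)

    def respond(stim):
        if stim.get("phase") == "study":
            return None, stim["study_s"]
        pick = good if rng.random() < p_correct else bad
        resp, _ = pick(stim)
        return resp, float(rng.uniform(0.5, 3.0))

    return respond


@pytest.fixture(scope="session")
def engine_config():
    return EngineConfig()


@pytest.fixture(scope="session")
def small_study():
    """A 14-participant simulated study reused across analysis tests."""
    cohort = sample_cohort(CohortSpec(n_bd=8, n_hv=6, seed=7))
    data = simulate_study(cohort, seed=7)
    battery = simulate_battery(cohort, seed=8)
    return cohort, data, battery
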