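"""1-up-1-down adaptive tracking of the stop-signal onset time (SSD).

After a successful stop the stop-signal moves 25 ms (one step) closer to the
target response time, making the next stop harder; after a failed stop it
moves one step earlier.  Tracked independently for each stop-signal
probability level, this holds each level's stop-success rate near 50 %.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["StaircaseState", "next_ssd", "Staircase"]


@dataclass(frozen=True)
class StaircaseState:
    level: int
    ssd: float                       # ms
    step: float = 25.0               # ms
    bounds: tuple[float, float] = (50.0, 775.0)
    history: tuple[tuple[float, bool], ...] = ()

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not self.bounds[0] <= self.ssd <= self.bounds[1]:
            raise ValueError("ssd outside bounds")


def next_ssd(state: StaircaseState, stop_success: bool) -> StaircaseState:
    """Advance one staircase step: up on success, down on failure, clamped."""
    delta = state.step if stop_success else -state.step
    new = min(max(state.ssd + delta, state.bounds[0]), state.bounds[1])
    return StaircaseState(
        level=state.level,
        ssd=new,
        step=state.step,
        bounds=state.bounds,
        history=state.history + ((state.ssd, bool(stop_success)),),
    )


class Staircase:
    """Mutable convenience wrapper around the immutable staircase state."""

    def __init__(self, level: int, ssd_init: float, step: float = 25.0,
                 bounds: tuple[float, float] = (50.0, 775.0)):
        self.state = StaircaseState(level=level, ssd=ssd_init, step=step, bounds=bounds)

    @property
    def ssd(self) -> float:
        return self.state.ssd

    def update(self, stop_success: bool) -> float:
        """Record the outcome at the current SSD and return the next SSD."""
        self.state = next_ssd(self.state, stop_success)
        return self.state.ssd

    def trajectory(self) -> pd.DataFrame:
        """Visited (ssd, outcome) pairs, one row per Stop trial, as a table."""
        rows = [
            {"trial": i, "level": self.state.level, "ssd": s, "outcome": int(ok)}
            for i, (s, ok) in enumerate(self.state.history)
        ]
        return pd.DataFrame(rows, columns=["trial", "level", "ssd", "outcome"])
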