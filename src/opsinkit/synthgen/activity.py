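"""Two-state persistent activity simulator with ethogram categories."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from opsinkit.behavior.core import (
    DEFAULT_CALENDAR,
    DEFAULT_SCHEDULE,
    ETHOGRAM_CATEGORIES,
    DayTypeCalendar,
    LightSchedule,
    annotate,
)


def _uniform_weights() -> dict[str, dict[str, float]]:
    w = {c: 1.0 / len(ETHOGRAM_CATEGORIES) for c in ETHOGRAM_CATEGORIES}
    return {"light": dict(w), "dark": dict(w)}


@dataclass
class ActivitySimParams:
    """Parameters of the per-minute activity simulation."""

    days: int = 27
    p_active_light: float = 0.5
    p_active_dark: float = 0.5
    persistence: float = 0.0
    category_weights: dict[str, dict[str, float]] = field(
        default_factory=_uniform_weights
    )
    schedule: LightSchedule = DEFAULT_SCHEDULE
    seed: int = 0
    individual: str = "sim01"
    start_date: date = date(2021, 11, 28)

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        for p in (self.p_active_light, self.p_active_dark):
            if not 0.0 <= p <= 1.0:
                raise ValueError("activity probabilities must lie in [0, 1]")
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must lie in [0, 1)")
        for cond in ("light", "dark"):
            weights = self.category_weights.get(cond)
            if not weights:
                raise ValueError(f"category_weights missing condition {cond!r}")
            total = sum(weights.values())
            if not np.isclose(total, 1.0):
                raise ValueError(
                    f"category_weights[{cond!r}] sums to {total}, expected 1"
                )


def simulate_activity(
    params: ActivitySimParams,
    calendar: DayTypeCalendar = DEFAULT_CALENDAR,
) -> pd.DataFrame:
    """Simulate a per-minute annotated activity table over `days` days.

    Minute-to-minute persistence: with probability `persistence` the
    previous active/nonactive state is retained, otherwise the state is
    drawn fresh with the condition's activity probability. Categories
    are drawn for active minutes from the condition's weights.
    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.days * 1440
    timestamps = pd.date_range(
        pd.Timestamp(params.start_date), periods=n, freq="min"
    )
    minute_of_day = timestamps.hour * 60 + timestamps.minute
    condition = params.schedule.condition_of_minute(minute_of_day.to_numpy())
    p_active = np.where(
        condition == "light", params.p_active_light, params.p_active_dark
    )

    fresh = rng.random(n) < p_active
    if params.persistence == 0.0:
        active = fresh
    else:
        keep = rng.random(n) < params.persistence
        active = np.empty(n, dtype=bool)
        active[0] = fresh[0]
        for t in range(1, n):
            active[t] = active[t - 1] if keep[t] else fresh[t]

    categories = np.full(n, "", dtype=object)
    for cond in ("light", "dark"):
        mask = active & (condition == cond)
        k = int(mask.sum())
        if k == 0:
            continue
        weights = params.category_weights[cond]
        names = list(weights)
        probs = np.array([weights[c] for c in names], dtype=float)
        categories[mask] = rng.choice(names, size=k, p=probs / probs.sum())

    table = pd.DataFrame(
        {
            "timestamp": timestamps,
            "individual": params.individual,
            "active": active.astype(int),
            "categories": categories,
        }
    )
    return annotate(table, params.schedule, calendar)
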