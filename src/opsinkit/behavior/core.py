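"""Per-minute activity tables: annotation, budgets and the two tests.

Tables are plain pandas DataFrames with columns
    timestamp (minute resolution), individual, active (0/1),
    categories (semicolon-joined codes, empty when nonactive)
plus, after `annotate`, condition (light|dark) and day_type
(closed|weekday|weekend). The light interval is closed-open
[light_on, light_off), wrapping across midnight when needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import time

import numpy as np
import pandas as pd
from scipy import stats as sps

ETHOGRAM_CATEGORIES = (
    "primary_behavior",
    "traveling",
    "halting",
    "searching",
    "self_treatment",
)

DAY_TYPES = ("closed", "weekday", "weekend")

REQUIRED_COLUMNS = ["timestamp", "individual", "active", "categories"]


def _minute_of_day(t: time) -> int:
    return t.hour * 60 + t.minute


@dataclass(frozen=True)
class LightSchedule:
    """Daily lighting schedule; light period is [light_on, light_off)."""

    light_on: time
    light_off: time

    def __post_init__(self) -> None:
        if self.light_on == self.light_off:
            raise ValueError("light_on and light_off must differ")

    @property
    def light_minutes_per_day(self) -> int:
        on, off = _minute_of_day(self.light_on), _minute_of_day(self.light_off)
        return off - on if off > on else 1440 - (on - off)

    @property
    def dark_minutes_per_day(self) -> int:
        return 1440 - self.light_minutes_per_day

    def condition_of_minute(self, minute_of_day) -> np.ndarray:
        """Vectorized light/dark label for minutes-of-day in [0, 1440)."""
        m = np.asarray(minute_of_day)
        on, off = _minute_of_day(self.light_on), _minute_of_day(self.light_off)
        if on < off:
            is_light = (m >= on) & (m < off)
        else:  # wraps midnight
            is_light = (m >= on) | (m < off)
        return np.where(is_light, "light", "dark")


#: 11 h of light from 22:47 to 09:47 (660 light / 780 dark minutes).
DEFAULT_SCHEDULE = LightSchedule(time(22, 47), time(9, 47))


@dataclass(frozen=True)
class DayTypeCalendar:
    """Maps weekday index (Monday=0) to a day type."""

    rule: dict[int, str] = field(
        default_factory=lambda: {
            0: "closed",
            1: "weekday", 2: "weekday", 3: "weekday", 4: "weekday",
            5: "weekend", 6: "weekend",
        }
    )

    def __post_init__(self) -> None:
        if set(self.rule) != set(range(7)):
            raise ValueError("calendar must cover all 7 weekdays")
        if not set(self.rule.values()) <= set(DAY_TYPES):
            raise ValueError(f"day types must be among {DAY_TYPES}")

    def day_type_of_weekday(self, weekday) -> np.ndarray:
        lut = np.array([self.rule[i] for i in range(7)])
        return lut[np.asarray(weekday)]


DEFAULT_CALENDAR = DayTypeCalendar()


def read_activity_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")
    df["categories"] = df["categories"].fillna("")
    return df


def annotate(
    table: pd.DataFrame,
    schedule: LightSchedule = DEFAULT_SCHEDULE,
    calendar: DayTypeCalendar = DEFAULT_CALENDAR,
) -> pd.DataFrame:
    """Fill condition and day_type for every record.

    Idempotent; raises on duplicate (individual, timestamp) pairs.
    """
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")
    if table.duplicated(subset=["individual", "timestamp"]).any():
        raise ValueError("duplicate (individual, timestamp) records")
    out = table.copy()
    ts = pd.to_datetime(out["timestamp"])
    minute = ts.dt.hour * 60 + ts.dt.minute
    out["condition"] = schedule.condition_of_minute(minute.to_numpy())
    out["day_type"] = calendar.day_type_of_weekday(ts.dt.weekday.to_numpy())
    return out


def _split_categories(series: pd.Series) -> pd.Series:
    return series.fillna("").astype(str).str.split(";")


def activity_budget(table: pd.DataFrame, by: str = "condition") -> pd.DataFrame:
    """Active-minute counts per individual, category and grouping column.

    A minute carrying k categories contributes 1 to each of the k
    category counts (multi-label rule).
    """
    if by not in table.columns:
        raise ValueError(f"grouping column {by!r} not in table (annotate first?)")
    active = table[table["active"].astype(bool)].copy()
    counts = []
    if not active.empty:
        exploded = active.assign(category=_split_categories(active["categories"]))
        exploded = exploded.explode("category")
        exploded = exploded[exploded["category"] != ""]
        counts = (
            exploded.groupby(["individual", by, "category"], observed=True)
            .size()
            .rename("minutes")
            .reset_index()
        )
    if len(counts) == 0:
        counts = pd.DataFrame(
            columns=["individual", by, "category", "minutes"]
        )
    return counts


def _paired_wilcoxon_p(diffs: np.ndarray) -> float:
    """Signed-rank p: zero differences excluded, exact null for n <= 25,
    normal approximation with continuity correction otherwise."""
    d = diffs[diffs != 0.0]
    n = d.size
    if n == 0:
        return 1.0
    ties = np.unique(np.abs(d)).size < n
    if n <= 25 and not ties:
        method = "exact"
    else:
        method = "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    return float(res.pvalue)


def lightdark_test(
    table: pd.DataFrame,
    schedule: LightSchedule = DEFAULT_SCHEDULE,
) -> pd.DataFrame:
    """Per-individual paired Wilcoxon test of daily activity frequency,
    light vs dark, with Bonferroni adjustment over the individuals.

    The pairing unit is the calendar day; frequency is active minutes
    divided by the minutes available in that condition, so the unequal
    light/dark durations do not bias the comparison. Individuals with
    fewer than 6 paired days are flagged underpowered but still tested.
    """
    if "condition" not in table.columns:
        raise ValueError("table must be annotated first")
    df = table.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.date
    avail = {
        "light": schedule.light_minutes_per_day,
        "dark": schedule.dark_minutes_per_day,
    }
    rows = []
    for individual, sub in df.groupby("individual"):
        daily = (
            sub.groupby(["date", "condition"], observed=True)["active"]
            .sum()
            .unstack("condition")
            .reindex(columns=["light", "dark"])
            .dropna()
        )
        freq_light = daily["light"].to_numpy() / avail["light"]
        freq_dark = daily["dark"].to_numpy() / avail["dark"]
        n_days = len(daily)
        p = _paired_wilcoxon_p(freq_light - freq_dark)
        rows.append(
            {
                "individual": individual,
                "n_days": n_days,
                "mean_freq_light": float(np.mean(freq_light)) if n_days else np.nan,
                "mean_freq_dark": float(np.mean(freq_dark)) if n_days else np.nan,
                "p_raw": p,
                "underpowered": n_days < 6,
            }
        )
    report = pd.DataFrame(rows)
    m = len(report)
    report["p_bonferroni"] = np.minimum(1.0, report["p_raw"] * m)
    return report


def daytype_chisq(table: pd.DataFrame, bin_hours: int = 3) -> pd.DataFrame:
    """Per-individual Pearson chi-squared test of active-minute counts
    across day types (rows) and time-of-day bins (columns).

    With the 3-h default and all three day types present the table is
    3 x 8, giving df = 14. Empty rows/columns are dropped with a warning
    and df recomputed.
    """
    if 24 % bin_hours:
        raise ValueError("bin_hours must divide 24")
    if "day_type" not in table.columns:
        raise ValueError("table must be annotated first")
    df = table[table["active"].astype(bool)].copy()
    ts = pd.to_datetime(df["timestamp"])
    df["bin"] = ts.dt.hour // bin_hours
    rows = []
    for individual, sub in df.groupby("individual"):
        ct = pd.crosstab(sub["day_type"], sub["bin"]).reindex(
            index=[t for t in DAY_TYPES if t in sub["day_type"].unique()],
            columns=range(24 // bin_hours),
            fill_value=0,
        )
        keep_rows = ct.sum(axis=1) > 0
        keep_cols = ct.sum(axis=0) > 0
        if not keep_rows.all() or not keep_cols.all():
            warnings.warn(
                f"{individual}: empty day-type rows or time bins dropped; "
                "df recomputed",
                stacklevel=2,
            )
            ct = ct.loc[keep_rows, keep_cols]
        chi2, p, dof, _ = sps.chi2_contingency(ct.to_numpy(), correction=False)
        rows.append(
            {
                "individual": individual,
                "N": int(ct.to_numpy().sum()),
                "chi2": float(chi2),
                "df": int(dof),
                "p": float(p),
                "n_day_types": ct.shape[0],
                "n_bins": ct.shape[1],
            }
        )
    return pd.DataFrame(rows)
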