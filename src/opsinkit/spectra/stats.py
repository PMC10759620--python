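"""Welch's unequal-variance t-test on replicate peaks or summary triples."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from opsinkit.spectra.core import LambdaMaxEstimate


@dataclass
class WelchResult:
    t_statistic: float
    df: float
    p_value: float
    group_summaries: tuple[tuple[float, float, int], tuple[float, float, int]]

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "group_summaries": [list(g) for g in self.group_summaries],
        }


def _as_summary(group) -> tuple[float, float, int]:
    """Accept a LambdaMaxEstimate, a (mean, sd, n) tuple, or raw samples.

    Dispatch is by type: tuples are summary triples; lists/arrays are
    raw per-replicate values.
    """
    if isinstance(group, LambdaMaxEstimate):
        return group.mean_nm, group.sd_nm, group.n
    if isinstance(group, tuple):
        if len(group) != 3:
            raise ValueError("summary tuple must be (mean, sd, n)")
        mean, sd, n = group
        return float(mean), float(sd), int(n)
    group = np.asarray(group, dtype=float)
    return (
        float(np.mean(group)),
        float(np.std(group, ddof=1)),
        int(group.size),
    )


def welch_t_test(a, b) -> WelchResult:
    """Two-sided Welch's t-test with Welch-Satterthwaite df.

    Each argument may be a LambdaMaxEstimate, a (mean, sd, n) triple, or
    a vector of raw per-replicate values (length != 3, or non-integral
    third element). Requires n >= 2 in both groups and not both SDs zero.
    """
    m1, s1, n1 = _as_summary(a)
    m2, s2, n2 = _as_summary(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch's t-test requires n >= 2 in both groups")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return WelchResult(0.0, float(n1 + n2 - 2), 1.0,
                               ((m1, s1, n1), (m2, s2, n2)))
        raise ValueError("both groups have zero variance but unequal means")
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p),
                       ((m1, s1, n1), (m2, s2, n2)))
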