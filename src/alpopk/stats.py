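"""Contingency-table comparisons of regimens: odds ratios, chi-square, NNT.

Tables are laid out as

                 event   no event
    treated        a        b
    control        c        d

The odds ratio uses the Woolf (log) 95 % confidence interval
``exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``; when any cell is zero
the Haldane–Anscombe +0.5 correction is applied to all four cells (if
enabled).  The chi-square statistic is the classic 1-df Pearson form
``n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``, with the Yates continuity
correction behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "ComparisonResult",
    "odds_ratio",
    "chi_square",
    "nnt",
    "counts_from_percent",
    "compare_all",
]

_Z95 = 1.959963984540054  # two-sided 95 % normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: (event, no-event) x (treated, control)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            val = getattr(self, name)
            if not isinstance(val, (int, np.integer)) or val < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {val!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class ComparisonResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi_square: float
    df: int
    p_value: float
    nnt: float | None = None
    n_treated: int | None = None
    n_control: int | None = None


def odds_ratio(
    table: ContingencyTable, zero_cell_correction: bool = True
) -> tuple[float, float, float]:
    """Odds ratio with Woolf 95 % CI; returns ``(or, ci_low, ci_high)``."""
    a, b, c, d = (float(x) for x in table.cells())
    if min(a, b, c, d) == 0.0:
        if not zero_cell_correction:
            raise ValueError("zero cell; enable zero_cell_correction or supply counts > 0")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValueError("both rows must have positive totals")
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        or_,
        or_ * math.exp(-_Z95 * se),
        or_ * math.exp(_Z95 * se),
    )


def chi_square(
    table: ContingencyTable, continuity_correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table; returns ``(X2, df=1, p)``."""
    a, b, c, d = (float(x) for x in table.cells())
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValueError("all row and column totals must be positive")
    diff = abs(a * d - b * c)
    if continuity_correction:
        diff = max(diff - n / 2.0, 0.0)
    x2 = n * diff**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(sps.chi2.sf(x2, df=1))
    return float(x2), 1, p


def nnt(p_control_event: float, p_treated_event: float) -> tuple[float, int]:
    """Number needed to treat: ``1 / (p_control - p_treated)``.

    Returns the unrounded value and its ceiling.  Undefined (error) when the
    treated event probability is not below the control probability.
    """
    for name, p in (("p_control_event", p_control_event), ("p_treated_event", p_treated_event)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    arr = p_control_event - p_treated_event
    if arr <= 0:
        raise ValueError("NNT undefined: treated event probability must be below control")
    value = 1.0 / arr
    return value, math.ceil(value)


def counts_from_percent(event_pct: float, n: int) -> tuple[int, int]:
    """Convert a simulated event percentage to (event, no-event) counts at an
    effective arm size ``n`` (rounded to the nearest whole patient)."""
    if not (0.0 <= event_pct <= 100.0):
        raise ValueError("percentage must lie in [0, 100]")
    events = int(round(n * event_pct / 100.0))
    return events, n - events


def _compare(
    treated_events: int, n_treated: int, control_events: int, n_control: int,
    zero_cell_correction: bool = True, continuity_correction: bool = False,
) -> ComparisonResult:
    table = ContingencyTable(
        treated_events, n_treated - treated_events,
        control_events, n_control - control_events,
    )
    or_, lo, hi = odds_ratio(table, zero_cell_correction)
    try:
        x2, df, p = chi_square(table, continuity_correction)
    except ValueError:  # a zero margin (e.g. no events in either arm)
        x2, df, p = float("nan"), 1, float("nan")
    nnt_value = None
    p_t, p_c = treated_events / n_treated, control_events / n_control
    if p_c > p_t:
        nnt_value = nnt(p_c, p_t)[0]
    return ComparisonResult(or_, lo, hi, x2, df, p, nnt_value, n_treated, n_control)


def compare_all(
    efficacy: pd.DataFrame,
    observed_control: dict[str, tuple[int, int]],
    n_effective: int = 13,
    zero_cell_correction: bool = True,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Compare every simulated regimen against the observed control arm and
    against every other regimen, per outcome.

    ``efficacy`` is a tidy table with ``daily_dose_mg``, ``adherence``,
    ``progression_pct`` and ``mortality_pct`` columns (one row per regimen
    condition); ``observed_control`` maps outcome name ('progression' /
    'mortality') to (events, arm size).  Simulated percentages are converted
    to counts at ``n_effective`` patients per simulated arm; every result row
    carries the arm sizes used.
    """
    outcome_cols = {"progression": "progression_pct", "mortality": "mortality_pct"}
    rows = []
    for outcome, col in outcome_cols.items():
        ctrl_events, ctrl_n = observed_control[outcome]
        for _, rec in efficacy.iterrows():
            ev, _ = counts_from_percent(rec[col], n_effective)
            res = _compare(ev, n_effective, ctrl_events, ctrl_n,
                           zero_cell_correction, continuity_correction)
            rows.append({
                "outcome": outcome, "comparison": "vs_control",
                "daily_dose_mg": rec["daily_dose_mg"],
                "reference_dose_mg": np.nan,
                "adherence": rec.get("adherence", 1.0),
                "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "chi_square": res.chi_square,
                "df": res.df, "p_value": res.p_value, "nnt": res.nnt,
                "n_treated": res.n_treated, "n_control": res.n_control,
            })
        for i, rec_i in efficacy.iterrows():
            for j, rec_j in efficacy.iterrows():
                if i == j or rec_i.get("adherence", 1.0) != rec_j.get("adherence", 1.0):
                    continue
                if rec_i["daily_dose_mg"] <= rec_j["daily_dose_mg"]:
                    continue
                ev_i, _ = counts_from_percent(rec_i[col], n_effective)
                ev_j, _ = counts_from_percent(rec_j[col], n_effective)
                res = _compare(ev_i, n_effective, ev_j, n_effective,
                               zero_cell_correction, continuity_correction)
                rows.append({
                    "outcome": outcome, "comparison": "vs_regimen",
                    "daily_dose_mg": rec_i["daily_dose_mg"],
                    "reference_dose_mg": rec_j["daily_dose_mg"],
                    "adherence": rec_i.get("adherence", 1.0),
                    "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "chi_square": res.chi_square,
                    "df": res.df, "p_value": res.p_value, "nnt": res.nnt,
                    "n_treated": res.n_treated, "n_control": res.n_control,
                })
    return pd.DataFrame(rows)
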