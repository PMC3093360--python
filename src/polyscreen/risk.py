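"""Age-conditional absolute risk under competing risks.

The probability of a cancer diagnosis between ages x and y, given alive
and cancer-free at x, is computed from piecewise-constant hazards with a
competing risk of death from other causes.  Within each one-year band
with scaled incidence ``lam = rr * lambda_c(a)`` and other-cause hazard
``dlt = lambda_o(a)``, the chance that the first event falls in the band
and is a diagnosis is ``lam / (lam + dlt) * (1 - exp(-(lam + dlt)))``,
the standard cause-specific decomposition of competing exponentials.
Summing band contributions weighted by the probability of entering each
band alive and cancer-free gives

    A(x, y | rr) = sum_{a=x}^{y-1} S(x, a) * lam/(lam+dlt) * (1 - e^{-(lam+dlt)})

with S(x, a) the survival (event-free) probability from x to a.  The
``rr`` multiplier scales cancer incidence only; other-cause mortality is
unaffected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .rates import RateTable, RateTableError

__all__ = ["age_conditional_risk", "event_free_survival", "risk_curve", "AbsoluteRiskCurve"]


def _check_window(table: RateTable, start_age: int, end_age: int, rr: float) -> None:
    if not (rr > 0.0) or not math.isfinite(rr):
        raise ValueError(f"rr must be positive and finite, got {rr!r}")
    if start_age >= end_age:
        raise ValueError(f"need start_age < end_age, got [{start_age}, {end_age})")
    if start_age < table.age_min or end_age > table.age_max + 1:
        raise RateTableError(
            f"window [{start_age}, {end_age}) outside table coverage "
            f"[{table.age_min}, {table.age_max + 1})"
        )


def age_conditional_risk(
    table: RateTable, start_age: int, end_age: int, rr: float = 1.0
) -> float:
    """Absolute risk of diagnosis in [start_age, end_age) given alive and
    cancer-free at start_age, for an individual at relative risk ``rr``."""
    _check_window(table, start_age, end_age, rr)
    i0 = start_age - table.age_min
    i1 = end_age - table.age_min
    lam_c = table.incidence
    lam_o = table.other_mortality
    # plain loop: bands are few and this sits inside root-finders
    surv = 1.0
    risk = 0.0
    for i in range(i0, i1):
        lam = rr * lam_c[i]
        dlt = lam_o[i]
        tot = lam + dlt
        if tot > 0.0:
            risk += surv * (lam / tot) * (-math.expm1(-tot))
            surv *= math.exp(-tot)
    return risk


def event_free_survival(
    table: RateTable, start_age: int, end_age: int, rr: float = 1.0
) -> float:
    """Probability of reaching end_age alive and cancer-free from start_age."""
    _check_window(table, start_age, end_age, rr)
    i0 = start_age - table.age_min
    i1 = end_age - table.age_min
    total = rr * float(np.sum(table.incidence[i0:i1])) + float(
        np.sum(table.other_mortality[i0:i1])
    )
    return math.exp(-total)


@dataclass(frozen=True)
class AbsoluteRiskCurve:
    """Absolute diagnosis risk over a fixed window, by starting age.

    Near the end of the table the window is truncated at
    ``age_max + 1``; ``end_ages`` records the truncation.
    """

    window_years: int
    rr: float
    start_ages: np.ndarray
    end_ages: np.ndarray
    risks: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_age": self.start_ages,
                "window_years": self.end_ages - self.start_ages,
                "rr": self.rr,
                "absolute_risk": self.risks,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    def at(self, start_age: int) -> float:
        idx = np.flatnonzero(self.start_ages == start_age)
        if idx.size == 0:
            raise KeyError(f"no curve value at start age {start_age}")
        return float(self.risks[idx[0]])


def risk_curve(table: RateTable, window: int = 10, rr: float = 1.0) -> AbsoluteRiskCurve:
    """Evaluate the windowed absolute risk at every feasible start age."""
    if window < 1:
        raise ValueError(f"window must be >= 1 year, got {window!r}")
    starts = np.arange(table.age_min, table.age_max + 1)
    ends = np.minimum(starts + window, table.age_max + 1)
    risks = np.array(
        [age_conditional_risk(table, int(x), int(y), rr) for x, y in zip(starts, ends)]
    )
    return AbsoluteRiskCurve(
        window_years=window, rr=rr, start_ages=starts, end_ages=ends, risks=risks
    )
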