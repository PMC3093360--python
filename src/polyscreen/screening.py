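"""Comparison of age-based and personalised screening eligibility.

Age-based screening makes everyone above an age cutoff eligible.
Personalised screening makes an individual eligible when their windowed
absolute risk — baseline incidence scaled by their polygenic relative
risk — reaches the same threshold ``t`` at their current age.  Because
windowed absolute risk is strictly increasing in the relative-risk
multiplier, eligibility at age ``a`` is equivalent to having relative
risk at or above the age-specific solution ``r*(a)`` of

    A(a, a + window | r) = t.

Eligible-population and potentially screen-detectable case fractions
follow by weighting the log-normal tail fractions above ``r*(a)`` by the
observed population and case counts per band.  "Potentially
screen-detectable" means only that a case arises inside the eligible
subgroup; no screening-test sensitivity model is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .distribution import PolygenicModel
from .rates import RateTable
from .risk import age_conditional_risk

__all__ = [
    "ALWAYS_ELIGIBLE",
    "NEVER_ELIGIBLE",
    "ScreeningPolicy",
    "StrategySummary",
    "ReclassificationTable",
    "threshold_rr_for_age",
    "strategy_summary",
    "reclassification",
    "threshold_sweep",
    "matched_threshold",
    "variance_fraction_sweep",
]

#: Sentinel returned by :func:`threshold_rr_for_age` when the risk
#: threshold is met even at a negligible relative risk (whole band
#: eligible) ...
ALWAYS_ELIGIBLE = 0.0
#: ... or is not met even at the top of the search range (nobody
#: eligible).
NEVER_ELIGIBLE = math.inf

_RR_LO = 1e-6
_RR_HI = 1e3


@dataclass(frozen=True)
class ScreeningPolicy:
    """Eligibility rule over an inclusive age range.

    ``kind`` is ``"age_based"`` (eligible from ``age_cutoff``) or
    ``"personalised"`` (eligible when windowed absolute risk reaches
    ``risk_threshold``).
    """

    kind: Literal["age_based", "personalised"]
    age_low: int
    age_high: int
    age_cutoff: int | None = None
    risk_threshold: float | None = None
    window: int = 10

    def __post_init__(self) -> None:
        if self.age_low > self.age_high:
            raise ValueError(f"empty age range [{self.age_low}, {self.age_high}]")
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window!r}")
        if self.kind == "age_based":
            if self.age_cutoff is None or not (
                self.age_low <= self.age_cutoff <= self.age_high
            ):
                raise ValueError(
                    f"age_cutoff {self.age_cutoff!r} must lie inside "
                    f"[{self.age_low}, {self.age_high}]"
                )
        elif self.kind == "personalised":
            t = self.risk_threshold
            if t is None or not (0.0 < t < 1.0):
                raise ValueError(f"risk_threshold must lie in (0, 1), got {t!r}")
        else:
            raise ValueError(f"unknown policy kind {self.kind!r}")

    @classmethod
    def age_based(cls, age_cutoff: int, age_range: tuple[int, int], window: int = 10):
        return cls("age_based", age_range[0], age_range[1], age_cutoff=age_cutoff, window=window)

    @classmethod
    def personalised(cls, risk_threshold: float, age_range: tuple[int, int], window: int = 10):
        return cls(
            "personalised", age_range[0], age_range[1],
            risk_threshold=risk_threshold, window=window,
        )


@dataclass(frozen=True)
class StrategySummary:
    """Fractions of the age-range population eligible for screening and
    of its cases arising within the eligible subgroup."""

    eligible_fraction: float
    detectable_case_fraction: float


def threshold_rr_for_age(
    table: RateTable, age: int, t: float, window: int = 10
) -> float:
    """Relative risk at which the windowed absolute risk at ``age``
    reaches the threshold ``t``.

    Solves ``A(age, age+window | r) = t`` by bracketed root-finding; the
    window is truncated at the table end.  Returns
    :data:`ALWAYS_ELIGIBLE` (0.0) if the threshold is met already at a
    negligible relative risk, or :data:`NEVER_ELIGIBLE` (inf) if it is
    unattainable within the search range — callers treat these as
    whole-band eligibility 1 or 0 rather than as errors.
    """
    if not (0.0 < t < 1.0):
        raise ValueError(f"risk threshold must lie in (0, 1), got {t!r}")
    end = min(age + window, table.age_max + 1)

    def gap(r: float) -> float:
        return age_conditional_risk(table, age, end, r) - t

    if gap(_RR_LO) >= 0.0:
        return ALWAYS_ELIGIBLE
    if gap(_RR_HI) < 0.0:
        return NEVER_ELIGIBLE
    # A is monotone increasing in rr; tight xtol keeps |A(r*) - t| ~ 1e-10
    return float(brentq(gap, _RR_LO, _RR_HI, xtol=1e-13, rtol=8.9e-16, maxiter=200))


def _tail_fraction(model: PolygenicModel, r_star: float, which: str) -> float:
    if r_star == ALWAYS_ELIGIBLE:
        return 1.0
    if r_star == NEVER_ELIGIBLE:
        return 0.0
    if which == "population":
        return model.population_fraction_above(r_star)
    return model.case_fraction_above(r_star)


def _band_eligibility(
    table: RateTable,
    model: PolygenicModel,
    ages: np.ndarray,
    t: float,
    window: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per band: population and case fractions above the age-specific
    eligibility relative risk r*(a)."""
    q_pop = np.empty(ages.size)
    q_case = np.empty(ages.size)
    for k, a in enumerate(ages):
        r_star = threshold_rr_for_age(table, int(a), t, window)
        q_pop[k] = _tail_fraction(model, r_star, "population")
        q_case[k] = _tail_fraction(model, r_star, "cases")
    return q_pop, q_case


def _range_arrays(table: RateTable, low: int, high: int):
    if low < table.age_min or high > table.age_max:
        raise ValueError(
            f"age range [{low}, {high}] outside table coverage "
            f"[{table.age_min}, {table.age_max}]"
        )
    sel = slice(low - table.age_min, high - table.age_min + 1)
    ages = table.ages[sel]
    return ages, table.population[sel], table.cancer_cases[sel]


def strategy_summary(
    table: RateTable, model: PolygenicModel, policy: ScreeningPolicy
) -> StrategySummary:
    """Eligible-population and screen-detectable case fractions for one policy.

    Case weights are the observed case counts per band, so the
    detectable-case fraction is the share of incident cases arising in
    the eligible subgroup.
    """
    ages, pop, cases = _range_arrays(table, policy.age_low, policy.age_high)
    if policy.kind == "age_based":
        mask = ages >= policy.age_cutoff
        return StrategySummary(
            eligible_fraction=float(pop[mask].sum() / pop.sum()),
            detectable_case_fraction=float(cases[mask].sum() / cases.sum()),
        )
    q_pop, q_case = _band_eligibility(
        table, model, ages, policy.risk_threshold, policy.window
    )
    return StrategySummary(
        eligible_fraction=float((pop * q_pop).sum() / pop.sum()),
        detectable_case_fraction=float((cases * q_case).sum() / cases.sum()),
    )


@dataclass(frozen=True)
class ReclassificationTable:
    """2x2 cross-tabulation of eligibility under the two strategies.

    Rows: risk-ineligible / risk-eligible; columns: below / at-or-above
    the age cutoff.  ``population`` is scaled to a standard population
    of 100,000 across the age range; ``cases`` uses the same scale, so
    its total is cases per 100,000 population.  Values are unrounded;
    use :meth:`to_frame` with ``rounded=True`` for presentation.
    """

    age_cutoff: int
    risk_threshold: float
    population: np.ndarray  # shape (2, 2)
    cases: np.ndarray  # shape (2, 2)

    @property
    def population_total(self) -> float:
        return float(self.population.sum())

    @property
    def cases_total(self) -> float:
        return float(self.cases.sum())

    def _frame(self, cells: np.ndarray, rounded: bool) -> pd.DataFrame:
        data = np.round(cells).astype(np.int64) if rounded else cells
        frame = pd.DataFrame(
            data,
            index=[f"risk < {self.risk_threshold:g}", f"risk >= {self.risk_threshold:g}"],
            columns=[f"age < {self.age_cutoff}", f"age >= {self.age_cutoff}"],
        )
        frame["total"] = frame.sum(axis=1)
        frame.loc["total"] = frame.sum(axis=0)
        return frame

    def to_frame(self, which: str = "population", rounded: bool = True) -> pd.DataFrame:
        if which not in ("population", "cases"):
            raise ValueError(f"which must be 'population' or 'cases', got {which!r}")
        cells = self.population if which == "population" else self.cases
        return self._frame(cells, rounded)


def reclassification(
    table: RateTable,
    model: PolygenicModel,
    age_policy: ScreeningPolicy,
    risk_policy: ScreeningPolicy,
) -> ReclassificationTable:
    """Cross-tabulate age eligibility against polygenic-risk eligibility.

    Both policies must share the age range and window.  Within each band
    the population splits by the tail fraction above r*(a) and the cases
    by the case tail fraction; bands are then assigned to the below/above
    age-cutoff column and everything is scaled to 100,000 population.
    """
    if (age_policy.age_low, age_policy.age_high) != (risk_policy.age_low, risk_policy.age_high):
        raise ValueError("policies must share the same age range")
    if age_policy.window != risk_policy.window:
        raise ValueError("policies must share the same risk window")
    if age_policy.kind != "age_based" or risk_policy.kind != "personalised":
        raise ValueError("expected an age_based and a personalised policy")

    ages, pop, cases = _range_arrays(table, age_policy.age_low, age_policy.age_high)
    q_pop, q_case = _band_eligibility(
        table, model, ages, risk_policy.risk_threshold, risk_policy.window
    )
    scale = 100_000.0 / pop.sum()
    old = ages >= age_policy.age_cutoff

    pop_cells = np.zeros((2, 2))
    case_cells = np.zeros((2, 2))
    for col, col_mask in enumerate((~old, old)):
        pop_cells[0, col] = (pop[col_mask] * (1.0 - q_pop[col_mask])).sum() * scale
        pop_cells[1, col] = (pop[col_mask] * q_pop[col_mask]).sum() * scale
        case_cells[0, col] = (cases[col_mask] * (1.0 - q_case[col_mask])).sum() * scale
        case_cells[1, col] = (cases[col_mask] * q_case[col_mask]).sum() * scale

    return ReclassificationTable(
        age_cutoff=int(age_policy.age_cutoff),
        risk_threshold=float(risk_policy.risk_threshold),
        population=pop_cells,
        cases=case_cells,
    )


def threshold_sweep(
    table: RateTable,
    model: PolygenicModel,
    age_range: tuple[int, int],
    thresholds: Sequence[float],
    window: int = 10,
) -> pd.DataFrame:
    """Personalised eligible and detectable-case fractions across a grid
    of absolute-risk thresholds."""
    rows = []
    for t in thresholds:
        policy = ScreeningPolicy.personalised(t, age_range, window)
        s = strategy_summary(table, model, policy)
        rows.append(
            {
                "risk_threshold": float(t),
                "eligible_fraction": s.eligible_fraction,
                "detectable_case_fraction": s.detectable_case_fraction,
            }
        )
    return pd.DataFrame(rows)


def matched_threshold(
    table: RateTable,
    model: PolygenicModel,
    age_policy: ScreeningPolicy,
    match: Literal["eligible_population", "detected_cases"] = "eligible_population",
    window: int | None = None,
    tol: float = 1e-6,
) -> float:
    """Risk threshold making the personalised strategy match the
    age-based one on eligible population or on detectable cases.

    Uses bracketed bisection on the (monotone decreasing) personalised
    fraction; the returned threshold reproduces the target fraction to
    within ``tol``.
    """
    if match not in ("eligible_population", "detected_cases"):
        raise ValueError(f"unknown match criterion {match!r}")
    window = age_policy.window if window is None else window
    age_range = (age_policy.age_low, age_policy.age_high)
    target_summary = strategy_summary(table, model, age_policy)
    target = (
        target_summary.eligible_fraction
        if match == "eligible_population"
        else target_summary.detectable_case_fraction
    )

    def fraction(t: float) -> float:
        s = strategy_summary(table, model, ScreeningPolicy.personalised(t, age_range, window))
        return s.eligible_fraction if match == "eligible_population" else s.detectable_case_fraction

    t_lo, t_hi = 1e-7, 0.95
    f_lo, f_hi = fraction(t_lo), fraction(t_hi)
    if not (f_hi - tol <= target <= f_lo + tol):
        raise ValueError(
            f"target fraction {target:.6f} unattainable; attainable range "
            f"[{f_hi:.6f}, {f_lo:.6f}] for thresholds in [{t_lo:g}, {t_hi:g}]"
        )
    t_star = float(brentq(lambda t: fraction(t) - target, t_lo, t_hi, xtol=1e-12, maxiter=200))
    got = fraction(t_star)
    if abs(got - target) > tol:
        # a degenerate (sigma2=0) model makes the fraction a step function
        # of t, so some targets fall inside a jump and cannot be attained
        raise ValueError(
            f"matched threshold did not attain target fraction {target:.6f}; "
            f"nearest attainable fraction {got:.6f}"
        )
    return t_star


def variance_fraction_sweep(
    table: RateTable,
    total_variance: float,
    fractions: Sequence[float],
    age_policy: ScreeningPolicy,
    match: Literal["eligible_population", "detected_cases"] = "detected_cases",
) -> pd.DataFrame:
    """Efficiency gain as a growing share of the polygenic variance is known.

    For each fraction ``f`` of ``total_variance``, finds the threshold at
    which the personalised strategy detects as many cases as the
    age-based one (or matches its eligible population), and reports the
    relative reduction in the eligible population.
    """
    if not (total_variance > 0.0):
        raise ValueError(f"total_variance must be positive, got {total_variance!r}")
    base = strategy_summary(table, PolygenicModel(0.0), age_policy)
    rows = []
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"variance fractions must lie in (0, 1], got {f!r}")
        model = PolygenicModel(f * total_variance)
        t_star = matched_threshold(table, model, age_policy, match=match)
        summary = strategy_summary(
            table,
            model,
            ScreeningPolicy.personalised(
                t_star, (age_policy.age_low, age_policy.age_high), age_policy.window
            ),
        )
        rows.append(
            {
                "fraction_known": float(f),
                "sigma2": model.sigma2,
                "matched_threshold": t_star,
                "eligible_fraction": summary.eligible_fraction,
                "detectable_case_fraction": summary.detectable_case_fraction,
                "eligible_reduction": 1.0 - summary.eligible_fraction / base.eligible_fraction,
            }
        )
    return pd.DataFrame(rows)
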