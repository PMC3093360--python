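"""Synthetic England-like rate tables and a cohort micro-simulator.

Real national registration and mortality extracts are not shipped;
instead this module generates rate tables with the qualitative shape of
English data — Gompertz (exponentially age-increasing) cancer incidence,
optionally flattening at a plateau age, and Gompertz all-cause mortality
— calibrated by root-finding the incidence scale so that the windowed
absolute risk hits an anchor (for example a 2% ten-year risk at age 55
for prostate-like rates, 2.5% at 47 for breast-like rates).

The cohort micro-simulator draws individual relative risks from a
:class:`~polyscreen.distribution.PolygenicModel` and walks subjects
through the age bands with competing exponential event times.  It is the
brute-force oracle for the closed-form quantities elsewhere in the
package.  Note one deliberate asymmetry: the closed-form model applies
the birth risk distribution at every age, whereas a longitudinal cohort
depletes high-risk subjects as they are diagnosed, so simulated case
risk distributions drift slightly below the closed form at old ages.
Cross-sectional simulation (fresh draws per band) matches the model's
own assumption and is provided for end-to-end checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .distribution import PolygenicModel
from .rates import RateTable
from .risk import age_conditional_risk

__all__ = [
    "DEFAULT_SEED",
    "SyntheticRateSpec",
    "prostate_rate_spec",
    "breast_rate_spec",
    "generate_rate_table",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_cross_section",
]

#: Default fixture seed; generation is deterministic (counts are derived
#: from hazards, not sampled) but the seed is recorded for provenance.
DEFAULT_SEED = 20110405


@dataclass(frozen=True)
class SyntheticRateSpec:
    """Parametric description of a synthetic rate table.

    Incidence follows ``lambda_c(a) = k * exp(g * min(a, plateau_age))``
    and other-cause mortality ``lambda_o(a) = m0 * exp(mg * a)``; ``k``
    is calibrated so that the absolute risk over
    ``(anchor_age, anchor_age + window)`` equals ``anchor_risk``.
    Hazards are evaluated at integer band start ages.
    """

    cancer: str
    sex: str
    age_min: int
    age_max: int
    incidence_slope: float
    anchor_age: int
    anchor_window: int
    anchor_risk: float
    plateau_age: int | None = None
    mortality_scale: float = 1.5e-5
    mortality_slope: float = 0.0975
    population_per_band: float = 100_000.0
    cancer_death_fraction: float = 0.2

    def ages(self) -> np.ndarray:
        return np.arange(self.age_min, self.age_max + 1)

    def incidence(self, scale: float) -> np.ndarray:
        a = self.ages().astype(float)
        if self.plateau_age is not None:
            a = np.minimum(a, float(self.plateau_age))
        return scale * np.exp(self.incidence_slope * a)

    def other_mortality(self) -> np.ndarray:
        a = self.ages().astype(float)
        return self.mortality_scale * np.exp(self.mortality_slope * a)


def prostate_rate_spec() -> SyntheticRateSpec:
    """Prostate-like rates: steep incidence flattening in the mid-70s,
    male all-cause mortality, anchored at 2% ten-year risk at age 55."""
    return SyntheticRateSpec(
        cancer="prostate",
        sex="male",
        age_min=35,
        age_max=89,
        incidence_slope=0.11,
        plateau_age=75,
        anchor_age=55,
        anchor_window=10,
        anchor_risk=0.02,
        mortality_scale=1.5e-5,
        mortality_slope=0.0975,
    )


def breast_rate_spec() -> SyntheticRateSpec:
    """Breast-like rates: incidence rising steeply to the mid-50s then
    flat, female all-cause mortality, anchored at 2.5% ten-year risk at
    age 47."""
    return SyntheticRateSpec(
        cancer="breast",
        sex="female",
        age_min=25,
        age_max=89,
        incidence_slope=0.08,
        plateau_age=55,
        anchor_age=47,
        anchor_window=10,
        anchor_risk=0.025,
        mortality_scale=1.0e-5,
        mortality_slope=0.0975,
    )


def _table_from_hazards(spec: SyntheticRateSpec, lam_c: np.ndarray) -> RateTable:
    lam_o = spec.other_mortality()
    pop = np.full(lam_c.shape, spec.population_per_band)
    cases = lam_c * pop
    cancer_deaths = spec.cancer_death_fraction * cases
    all_deaths = lam_o * pop + cancer_deaths
    return RateTable(
        cancer=spec.cancer,
        sex=spec.sex,
        ages=spec.ages(),
        population=pop,
        cancer_cases=cases,
        cancer_deaths=cancer_deaths,
        all_cause_deaths=all_deaths,
    )


def generate_rate_table(
    spec: SyntheticRateSpec, seed: int = DEFAULT_SEED, round_counts: bool = True
) -> RateTable:
    """Build a calibrated synthetic rate table.

    Root-finds the incidence scale so the anchor absolute risk is met to
    1e-10 on the continuous hazards; counts are then back-computed at
    ``population_per_band`` person-years per band and (by default)
    rounded to integers, which perturbs the realised anchor risk by at
    most O(1 / population_per_band).  Deterministic; ``seed`` is
    accepted for interface symmetry with the simulator.
    """
    if spec.anchor_age < spec.age_min or spec.anchor_age + spec.anchor_window > spec.age_max + 1:
        raise ValueError("calibration anchor window outside the generated age range")
    if not (0.0 < spec.anchor_risk < 1.0):
        raise ValueError(f"anchor risk must lie in (0, 1), got {spec.anchor_risk!r}")

    def anchored_risk(log_scale: float) -> float:
        table = _table_from_hazards(spec, spec.incidence(math.exp(log_scale)))
        return age_conditional_risk(
            table, spec.anchor_age, spec.anchor_age + spec.anchor_window
        )

    lo, hi = math.log(1e-12), math.log(1e-1)
    if not (anchored_risk(lo) < spec.anchor_risk < anchored_risk(hi)):
        raise ValueError(
            f"anchor risk {spec.anchor_risk} unattainable; attainable range "
            f"({anchored_risk(lo):.3e}, {anchored_risk(hi):.3e})"
        )
    log_k = brentq(
        lambda s: anchored_risk(s) - spec.anchor_risk, lo, hi, xtol=1e-14, maxiter=200
    )
    table = _table_from_hazards(spec, spec.incidence(math.exp(log_k)))
    if not round_counts:
        return table
    return RateTable(
        cancer=table.cancer,
        sex=table.sex,
        ages=table.ages,
        population=table.population,
        cancer_cases=np.round(table.cancer_cases),
        cancer_deaths=np.round(table.cancer_deaths),
        all_cause_deaths=np.round(table.all_cause_deaths),
    )


# ---------------------------------------------------------------------------
# cohort micro-simulation
# ---------------------------------------------------------------------------

CENSORED, CANCER, OTHER_DEATH = 0, 1, 2


@dataclass(frozen=True)
class SimulatedCohort:
    """Individual-level simulation results.

    Per subject: the relative risk drawn at entry, the integer age band
    of the first event, and the event type (0 censored at ``end_age``,
    1 cancer diagnosis, 2 other-cause death).  ``event_age`` for
    censored subjects equals ``end_age``.
    """

    start_age: int
    end_age: int
    seed: int
    rr: np.ndarray
    event_age: np.ndarray
    event_type: np.ndarray

    @property
    def n(self) -> int:
        return int(self.rr.size)

    def absolute_risk(self, start_age: int, end_age: int) -> tuple[float, float]:
        """Empirical A(start, end) with its binomial standard error.

        Conditions on being alive and cancer-free entering ``start_age``.
        """
        at_risk = self.event_age >= start_age
        m = int(at_risk.sum())
        if m == 0:
            raise ValueError(f"no subjects at risk at age {start_age}")
        hit = at_risk & (self.event_type == CANCER) & (self.event_age < end_age)
        p = hit.sum() / m
        return float(p), float(math.sqrt(max(p * (1.0 - p), 1e-300) / m))

    def case_log_rr(self, max_age: int | None = None) -> np.ndarray:
        """Log relative risks of subjects diagnosed before ``max_age``."""
        mask = self.event_type == CANCER
        if max_age is not None:
            mask &= self.event_age < max_age
        return np.log(self.rr[mask])


def simulate_cohort(
    table: RateTable,
    model: PolygenicModel,
    n: int,
    seed: int,
    start_age: int | None = None,
    end_age: int | None = None,
    fixed_rr: float | None = None,
) -> SimulatedCohort:
    """Simulate ``n`` subjects through the age bands of ``table``.

    Each subject receives a relative risk drawn from ``model`` (or the
    common ``fixed_rr``), then experiences band-wise competing
    exponential hazards ``(rr * lambda_c, lambda_o)``; the first event
    ends follow-up.  Reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 subjects, got {n!r}")
    start = table.age_min if start_age is None else int(start_age)
    end = table.age_max + 1 if end_age is None else int(end_age)
    if not (table.age_min <= start < end <= table.age_max + 1):
        raise ValueError(f"simulation window [{start}, {end}) outside table coverage")

    rng = np.random.default_rng(seed)
    if fixed_rr is not None:
        if not (fixed_rr > 0.0):
            raise ValueError(f"fixed_rr must be positive, got {fixed_rr!r}")
        rr = np.full(n, float(fixed_rr))
    elif model.sigma2 == 0.0:
        rr = np.ones(n)
    else:
        rr = np.exp(rng.normal(model.mu, model.sigma, size=n))

    event_age = np.full(n, end, dtype=np.int32)
    event_type = np.zeros(n, dtype=np.int8)
    alive = np.arange(n)

    for a in range(start, end):
        lam_c, lam_o = table.hazards(a)
        lam = rr[alive] * lam_c
        tot = lam + lam_o
        p_event = -np.expm1(-tot)
        u = rng.random(alive.size)
        hit = u < p_event
        if hit.any():
            idx = alive[hit]
            # conditional on an event, its cause is cancer w.p. lam/tot
            cause = rng.random(idx.size) < (lam[hit] / tot[hit])
            event_age[idx] = a
            event_type[idx] = np.where(cause, CANCER, OTHER_DEATH)
            alive = alive[~hit]
            if alive.size == 0:
                break

    return SimulatedCohort(
        start_age=start, end_age=end, seed=int(seed),
        rr=rr, event_age=event_age, event_type=event_type,
    )


def simulate_cross_section(
    table: RateTable,
    model: PolygenicModel,
    age: int,
    n: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one band cross-sectionally: a fresh population at ``age``.

    Draws ``n`` relative risks from the birth distribution (the model's
    assumption for every age), exposes each subject to one band of
    competing hazards, and returns ``(rr, diagnosed_mask)``.  Used as an
    oracle for per-band case risk distributions free of longitudinal
    depletion.
    """
    rng = np.random.default_rng(seed)
    rr = (
        np.ones(n)
        if model.sigma2 == 0.0
        else np.exp(rng.normal(model.mu, model.sigma, size=n))
    )
    lam_c, lam_o = table.hazards(age)
    lam = rr * lam_c
    tot = lam + lam_o
    with np.errstate(divide="ignore", invalid="ignore"):
        p_cancer = np.where(tot > 0.0, (lam / np.where(tot > 0, tot, 1.0)) * -np.expm1(-tot), 0.0)
    diagnosed = rng.random(n) < p_cancer
    return rr, diagnosed
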