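"""Log-normal distribution of polygenic relative risk.

Summing many small log-additive allele effects makes log relative risk
approximately normal, so relative risk RR in the population at birth is
modelled as log-normal with variance ``sigma2`` and mean
``mu = -sigma2 / 2``, which fixes the population mean relative risk at
exactly one.

Because cases arise in proportion to their relative risk, the risk
distribution among cases is the size-biased version of the population
distribution.  For a log-normal this is again log-normal with the same
variance, shifted right on the log scale by ``sigma2``.  The shift is
derived for incident cases before appreciable depletion of susceptibles
and is applied at all ages, a simplification the rest of the package
inherits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["PolygenicModel"]


@dataclass(frozen=True)
class PolygenicModel:
    """Log-normal relative-risk model parameterised by its variance.

    ``sigma2`` is the variance of log relative risk; the log-scale mean
    is always ``-sigma2 / 2`` so that E[RR] = 1.  ``sigma2 = 0`` is the
    degenerate limit (everyone at RR = 1), under which risk-stratified
    eligibility provably collapses to age-only eligibility.
    """

    sigma2: float

    def __post_init__(self) -> None:
        if not (self.sigma2 >= 0.0) or not math.isfinite(self.sigma2):
            raise ValueError(f"sigma2 must be finite and >= 0, got {self.sigma2!r}")

    @property
    def mu(self) -> float:
        """Mean of log relative risk (fixed normalisation)."""
        return -self.sigma2 / 2.0

    @property
    def sigma(self) -> float:
        return math.sqrt(self.sigma2)

    # -- tail fractions -------------------------------------------------

    def population_fraction_above(self, rr_threshold: float) -> float:
        """Fraction of the population with relative risk above a threshold.

        Returns ``1 - Phi((ln r - mu) / sigma)``; for ``sigma2 = 0`` a
        step function (1 if r <= 1 else 0).
        """
        r = self._check_threshold(rr_threshold)
        if self.sigma2 == 0.0:
            return 1.0 if r <= 1.0 else 0.0
        return float(norm.sf((math.log(r) - self.mu) / self.sigma))

    def case_fraction_above(self, rr_threshold: float) -> float:
        """Fraction of cases arising among those above a risk threshold.

        The case distribution is the population one shifted right by
        ``sigma2`` on the log scale, so this is
        ``1 - Phi((ln r - mu - sigma2) / sigma)``.
        """
        r = self._check_threshold(rr_threshold)
        if self.sigma2 == 0.0:
            return 1.0 if r <= 1.0 else 0.0
        return float(norm.sf((math.log(r) - self.mu - self.sigma2) / self.sigma))

    # -- quantiles ------------------------------------------------------

    def rr_quantile(self, q: float, which: str = "population") -> float:
        """Relative risk at a given quantile of either distribution.

        Inverse of the corresponding CDF; ``which`` is ``"population"``
        or ``"cases"``.
        """
        if not (0.0 < q < 1.0):
            raise ValueError(f"quantile must lie in (0, 1), got {q!r}")
        if which not in ("population", "cases"):
            raise ValueError(f"which must be 'population' or 'cases', got {which!r}")
        if self.sigma2 == 0.0:
            return 1.0
        shift = self.sigma2 if which == "cases" else 0.0
        return math.exp(self.mu + shift + self.sigma * float(norm.ppf(q)))

    # -- densities (used by quadrature checks and plots) ----------------

    def population_pdf(self, r: float) -> float:
        """Log-normal density of relative risk in the population."""
        if r <= 0.0:
            return 0.0
        if self.sigma2 == 0.0:
            raise ValueError("degenerate model has no density")
        z = (math.log(r) - self.mu) / self.sigma
        return math.exp(-0.5 * z * z) / (r * self.sigma * math.sqrt(2.0 * math.pi))

    def case_pdf(self, r: float) -> float:
        """Density of relative risk among cases (size-biased)."""
        if r <= 0.0:
            return 0.0
        if self.sigma2 == 0.0:
            raise ValueError("degenerate model has no density")
        z = (math.log(r) - self.mu - self.sigma2) / self.sigma
        return math.exp(-0.5 * z * z) / (r * self.sigma * math.sqrt(2.0 * math.pi))

    @staticmethod
    def _check_threshold(rr_threshold: float) -> float:
        r = float(rr_threshold)
        if not (r > 0.0) or not math.isfinite(r):
            raise ValueError(f"rr_threshold must be positive and finite, got {rr_threshold!r}")
        return r
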