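"""Population rate tables in one-year age bands.

A rate table carries, per band [a, a+1), pooled person-years of
observation and event counts: cancer registrations, cancer deaths and
all-cause deaths.  From these it derives piecewise-constant hazards

    lambda_c(a) = cancer_cases / person_years          (incidence)
    lambda_o(a) = (all_deaths - cancer_deaths) / py    (other-cause death)

Other-cause mortality among the cancer-free is approximated by
subtracting cancer deaths from all-cause deaths over total person-years;
no correction is made for person-years lived with prevalent cancer.
Multi-year pooled data are expected to arrive already summed over years.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RateTable",
    "RateTableError",
    "load_rate_table",
    "packaged_rate_table",
]

RATE_COLUMNS = ["age", "population", "cancer_cases", "cancer_deaths", "all_cause_deaths"]


class RateTableError(ValueError):
    """Raised when a rate table violates its invariants."""


@dataclass(frozen=True)
class RateTable:
    """Contiguous one-year age bands with derived hazards.

    Bands are half-open ``[a, a+1)``; an inclusive age range "55-79"
    therefore spans bands 55 through 79.  Arrays are aligned so index
    ``a - age_min`` addresses band ``a``.
    """

    cancer: str
    sex: str
    ages: np.ndarray
    population: np.ndarray
    cancer_cases: np.ndarray
    cancer_deaths: np.ndarray
    all_cause_deaths: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        if ages.size == 0:
            raise RateTableError("rate table has no age bands")
        if not np.array_equal(np.diff(ages), np.ones(ages.size - 1, dtype=int)):
            raise RateTableError("age bands must be contiguous 1-year bands (non-contiguous ages)")
        for name in ("population", "cancer_cases", "cancer_deaths", "all_cause_deaths"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != ages.shape:
                raise RateTableError(f"{name} length does not match ages")
            if not np.all(np.isfinite(arr)):
                raise RateTableError(f"{name} contains non-finite values")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "ages", ages)
        bad = np.flatnonzero(self.population <= 0)
        if bad.size:
            raise RateTableError(f"non-positive population in band age {ages[bad[0]]}")
        for name in ("cancer_cases", "cancer_deaths", "all_cause_deaths"):
            bad = np.flatnonzero(getattr(self, name) < 0)
            if bad.size:
                raise RateTableError(f"negative {name} in band age {ages[bad[0]]}")
        bad = np.flatnonzero(self.cancer_deaths > self.all_cause_deaths)
        if bad.size:
            raise RateTableError(
                f"cancer_deaths exceed all_cause_deaths in band age {ages[bad[0]]}"
            )

    # -- basic accessors ------------------------------------------------

    @property
    def age_min(self) -> int:
        return int(self.ages[0])

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    def __len__(self) -> int:
        return int(self.ages.size)

    @property
    def incidence(self) -> np.ndarray:
        """Cancer incidence hazard per band, cases / person-years."""
        return self.cancer_cases / self.population

    @property
    def other_mortality(self) -> np.ndarray:
        """Other-cause death hazard per band."""
        return (self.all_cause_deaths - self.cancer_deaths) / self.population

    def _index(self, age: int) -> int:
        if not (self.age_min <= age <= self.age_max):
            raise RateTableError(
                f"age {age} outside table coverage [{self.age_min}, {self.age_max}]"
            )
        return int(age) - self.age_min

    def hazards(self, age: int) -> tuple[float, float]:
        """``(lambda_c, lambda_o)`` for the band starting at ``age``."""
        i = self._index(age)
        return float(self.incidence[i]), float(self.other_mortality[i])

    # -- I/O -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "population": self.population,
                "cancer_cases": self.cancer_cases,
                "cancer_deaths": self.cancer_deaths,
                "all_cause_deaths": self.all_cause_deaths,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        # integral counts are written as integers so files round-trip textually
        for col in frame.columns:
            vals = frame[col].to_numpy()
            if np.allclose(vals, np.round(vals)):
                frame[col] = np.round(vals).astype(np.int64)
        frame.to_csv(path, index=False, lineterminator="\n")


def load_rate_table(path: str | Path, cancer: str = "", sex: str = "") -> RateTable:
    """Read and validate a rate-table CSV.

    Expected header ``age,population,cancer_cases,cancer_deaths,
    all_cause_deaths``, one row per one-year band, ages ascending.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise RateTableError(f"could not parse rate CSV {path}: {exc}") from exc
    missing = [c for c in RATE_COLUMNS if c not in frame.columns]
    if missing:
        raise RateTableError(f"rate CSV {path} missing columns: {', '.join(missing)}")
    if frame.empty:
        raise RateTableError(f"rate CSV {path} has no bands")
    return RateTable(
        cancer=cancer,
        sex=sex,
        ages=frame["age"].to_numpy(dtype=int),
        population=frame["population"].to_numpy(dtype=float),
        cancer_cases=frame["cancer_cases"].to_numpy(dtype=float),
        cancer_deaths=frame["cancer_deaths"].to_numpy(dtype=float),
        all_cause_deaths=frame["all_cause_deaths"].to_numpy(dtype=float),
    )


def packaged_rate_table(cancer: str) -> RateTable:
    """Load a shipped synthetic rate table: ``"prostate"`` or ``"breast"``.

    These are generated, England-like fixtures (see
    :mod:`polyscreen.synthetic`), not real registration data.
    """
    names = {
        "prostate": ("synthetic_prostate_rates.csv", "male"),
        "breast": ("synthetic_breast_rates.csv", "female"),
    }
    if cancer not in names:
        raise ValueError(f"no packaged rates for {cancer!r}; choose from {sorted(names)}")
    fname, sex = names[cancer]
    with resources.as_file(resources.files("polyscreen.data").joinpath(fname)) as path:
        return load_rate_table(path, cancer=cancer, sex=sex)
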