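"""Susceptibility-locus panels and the polygenic variance they confer.

Common cancer susceptibility variants found by GWAS each carry a small
per-allele effect.  Under a log-additive model with Hardy-Weinberg
genotype frequencies, a biallelic locus with risk-allele frequency ``p``
and per-allele odds ratio ``OR`` contributes

    2 p (1 - p) [ln OR]^2

to the variance of log relative risk in the population, and independent
loci contribute additively.  That total variance is the single parameter
of the log-normal risk model in :mod:`polyscreen.distribution`.

Per-allele odds ratios are treated as relative risks on the log scale,
which is adequate for diseases with small per-year incidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = [
    "SusceptibilityLocus",
    "LocusPanel",
    "PanelValidationError",
    "locus_variance",
    "panel_variance",
    "familial_risk_fraction",
    "load_panel",
    "packaged_panel",
    "round_half_away",
]

PANEL_COLUMNS = ["rsid", "locus", "risk_allele_freq", "or_per_allele"]
OPTIONAL_COLUMNS = ["chromosome_class"]


class PanelValidationError(ValueError):
    """Raised when a locus or panel violates its invariants."""


def round_half_away(value: float, ndigits: int = 3) -> float:
    """Round with ties going away from zero (display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SusceptibilityLocus:
    """One biallelic susceptibility variant.

    Parameters
    ----------
    rsid : str
        dbSNP identifier; unique within a panel.
    locus_label : str
        Cytoband / candidate gene, informational only.
    risk_allele_freq : float
        Population frequency of the risk allele, strictly in (0, 1).
    or_per_allele : float
        Per-allele odds ratio, strictly positive.  Values below one are
        allowed; the variance contribution is symmetric in ln OR.
    chromosome_class : str
        ``"autosomal"`` or ``"x_linked"``; informational unless the
        hemizygous variance option is enabled.
    """

    rsid: str
    locus_label: str = ""
    risk_allele_freq: float = 0.5
    or_per_allele: float = 1.0
    chromosome_class: str = "autosomal"

    def __post_init__(self) -> None:
        if not self.rsid:
            raise PanelValidationError("locus requires a non-empty rsid")
        p = self.risk_allele_freq
        if not (0.0 < p < 1.0) or not math.isfinite(p):
            raise PanelValidationError(
                f"{self.rsid}: risk_allele_freq must lie in (0, 1), got {p!r}"
            )
        orr = self.or_per_allele
        if not (orr > 0.0) or not math.isfinite(orr):
            raise PanelValidationError(
                f"{self.rsid}: or_per_allele must be positive, got {orr!r}"
            )
        if self.chromosome_class not in ("autosomal", "x_linked"):
            raise PanelValidationError(
                f"{self.rsid}: chromosome_class must be 'autosomal' or "
                f"'x_linked', got {self.chromosome_class!r}"
            )


def locus_variance(
    locus: SusceptibilityLocus, *, x_linked_hemizygous: bool = False
) -> float:
    """Variance of log relative risk contributed by one locus.

    Returns ``2 p (1-p) [ln OR]^2`` for a biallelic locus under
    Hardy-Weinberg equilibrium and a log-additive model.  If
    ``x_linked_hemizygous`` is set, X-linked loci use the single-allele
    form ``p (1-p) [ln OR]^2`` appropriate for hemizygous males.
    """
    p = locus.risk_allele_freq
    beta2 = math.log(locus.or_per_allele) ** 2
    copies = 1.0 if (x_linked_hemizygous and locus.chromosome_class == "x_linked") else 2.0
    return copies * p * (1.0 - p) * beta2


@dataclass(frozen=True)
class LocusPanel:
    """An ordered collection of susceptibility loci for one cancer."""

    cancer: str
    loci: tuple[SusceptibilityLocus, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.loci:
            raise PanelValidationError(f"empty panel for cancer {self.cancer!r}")
        seen: dict[str, int] = {}
        for locus in self.loci:
            if locus.rsid in seen:
                raise PanelValidationError(f"duplicate rsid {locus.rsid!r} in panel")
            seen[locus.rsid] = 1

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[SusceptibilityLocus]:
        return iter(self.loci)

    def variance(self, *, x_linked_hemizygous: bool = False) -> float:
        return panel_variance(self, x_linked_hemizygous=x_linked_hemizygous)

    def summary(self, *, x_linked_hemizygous: bool = False) -> pd.DataFrame:
        """Per-locus table with recomputed variance contributions.

        Variances are recomputed from allele frequency and odds ratio;
        the panel fixtures deliberately do not carry published per-locus
        variance columns (several published cells are inconsistent with
        their own frequency / odds-ratio pairs).
        """
        rows = []
        for locus in self.loci:
            v = locus_variance(locus, x_linked_hemizygous=x_linked_hemizygous)
            rows.append(
                {
                    "rsid": locus.rsid,
                    "locus": locus.locus_label,
                    "risk_allele_freq": locus.risk_allele_freq,
                    "or_per_allele": locus.or_per_allele,
                    "variance": v,
                    "variance_3dp": round_half_away(v, 3),
                }
            )
        return pd.DataFrame(rows)


def panel_variance(panel: LocusPanel, *, x_linked_hemizygous: bool = False) -> float:
    """Total polygenic variance: sum of per-locus contributions.

    Loci are assumed independent (no linkage-disequilibrium
    adjustment), so variances add.
    """
    if not panel.loci:  # pragma: no cover - LocusPanel forbids this
        raise PanelValidationError("cannot compute variance of an empty panel")
    return sum(
        locus_variance(locus, x_linked_hemizygous=x_linked_hemizygous)
        for locus in panel.loci
    )


def familial_risk_fraction(known_variance: float, total_variance: float) -> float:
    """Share of the familial (polygenic) risk explained by known variants.

    Under the log-normal polygenic model the log familial relative risk
    is proportional to the polygenic variance, so the explained fraction
    is simply ``known_variance / total_variance``.
    """
    if not (total_variance > 0.0):
        raise ValueError(f"total_variance must be positive, got {total_variance!r}")
    if known_variance < 0.0:
        raise ValueError(f"known_variance must be non-negative, got {known_variance!r}")
    if known_variance > total_variance:
        raise ValueError(
            f"known_variance ({known_variance!r}) exceeds total_variance "
            f"({total_variance!r})"
        )
    return known_variance / total_variance


def _read_panel_frame(path: Path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except Exception as exc:  # malformed CSV
        raise PanelValidationError(f"could not parse panel CSV {path}: {exc}") from exc
    missing = [c for c in PANEL_COLUMNS if c not in frame.columns]
    if missing:
        raise PanelValidationError(
            f"panel CSV {path} missing required columns: {', '.join(missing)}"
        )
    return frame


def load_panel(path: str | Path, cancer: str = "custom") -> LocusPanel:
    """Load and validate a susceptibility panel from CSV.

    Expected header ``rsid,locus,risk_allele_freq,or_per_allele`` with an
    optional ``chromosome_class`` column.  All rows are validated and a
    single error listing every offending row (with its CSV line number)
    is raised if any fail.
    """
    path = Path(path)
    frame = _read_panel_frame(path)
    if frame.empty:
        raise PanelValidationError(f"empty panel: {path} has a header but no loci")

    errors: list[str] = []
    loci: list[SusceptibilityLocus] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # header is line 1
        rsid = (row.get("rsid") or "").strip()
        try:
            p = float(row["risk_allele_freq"])
            orr = float(row["or_per_allele"])
        except (TypeError, ValueError):
            errors.append(f"line {line} ({rsid or '?'}): non-numeric frequency or OR")
            continue
        chrom = (row.get("chromosome_class") or "autosomal").strip() or "autosomal"
        try:
            locus = SusceptibilityLocus(
                rsid=rsid,
                locus_label=(row.get("locus") or "").strip(),
                risk_allele_freq=p,
                or_per_allele=orr,
                chromosome_class=chrom,
            )
        except PanelValidationError as exc:
            errors.append(f"line {line}: {exc}")
            continue
        if locus.rsid in seen:
            errors.append(f"line {line}: duplicate rsid {locus.rsid!r}")
            continue
        seen.add(locus.rsid)
        loci.append(locus)
    if errors:
        raise PanelValidationError(
            f"invalid panel {path}:\n  " + "\n  ".join(errors)
        )
    return LocusPanel(cancer=cancer, loci=tuple(loci))


def packaged_panel(cancer: str) -> LocusPanel:
    """Load one of the shipped panels: ``"prostate"`` (31 loci) or
    ``"breast"`` (18 loci)."""
    names = {"prostate": "prostate_31.csv", "breast": "breast_18.csv"}
    if cancer not in names:
        raise ValueError(f"no packaged panel for {cancer!r}; choose from {sorted(names)}")
    with resources.as_file(
        resources.files("polyscreen.data").joinpath(names[cancer])
    ) as path:
        return load_panel(path, cancer=cancer)
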