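"""Pathway-utilization statistics from per-sterol synthesis rates.

Cholesterol can be completed through two terminal branches: the Bloch route
(via desmosterol) or the modified Kandutsch-Russell route (via
7-dehydrocholesterol). Fractional Bloch utilization is the desmosterol
synthesis rate divided by the sum of the desmosterol and
7-dehydrocholesterol rates. A secondary, lanosterol-denominated ratio
(desmosterol rate / lanosterol rate) differs wherever flux exits the
pathway upstream (e.g. diversion of t-MAS in testes), which is itself
diagnostic: ratios of adjacent measurable intermediates localize where flux
leaves the main line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, QuantitationError
from .registry import BLOCH_ORDER, KR_ORDER, SterolRegistry

__all__ = ["PathwayReport", "SegmentFlag", "bloch_fraction", "bloch_fraction_alt",
           "flux_drop_diagnostics", "utilization_vs_logflux",
           "tracer_conversion_summary"]

#: Downstream/upstream rate ratio below which a segment is flagged as a
#: diversion point.
FLUX_DROP_THRESHOLD = 0.67


def bloch_fraction(rate_desmosterol: float, rate_7dhc: float) -> float:
    """Fraction of terminal cholesterol synthesis carried by the Bloch branch."""
    if rate_desmosterol < 0 or rate_7dhc < 0:
        raise InvalidInputError("rates must be >= 0")
    total = rate_desmosterol + rate_7dhc
    if total <= 0:
        raise InvalidInputError("sum of terminal rates is zero; fraction undefined")
    return rate_desmosterol / total


def bloch_fraction_alt(rate_desmosterol: float, rate_lanosterol: float) -> float:
    """Lanosterol-denominated utilization ratio (desmosterol / lanosterol).

    Differs from :func:`bloch_fraction` where flux exits the pathway between
    lanosterol and the terminal branch point.
    """
    if rate_lanosterol <= 0:
        raise InvalidInputError("lanosterol rate is zero; ratio undefined")
    if rate_desmosterol < 0:
        raise InvalidInputError("rates must be >= 0")
    return rate_desmosterol / rate_lanosterol


@dataclass(frozen=True)
class SegmentFlag:
    """Flux ratio across one adjacent pair of measurable intermediates."""

    upstream: str
    downstream: str
    ratio: float
    flagged: bool
    branch: str              # "bloch" or "kr"


def flux_drop_diagnostics(rates: dict[str, float], registry: SterolRegistry,
                          threshold: float = FLUX_DROP_THRESHOLD,
                          ) -> list[SegmentFlag]:
    """Scan both branches for flux drops between adjacent measurable sterols.

    For each adjacent pair present in ``rates`` with a positive upstream
    rate, reports downstream/upstream; ratios below ``threshold`` are flagged
    as candidate diversion points. Missing sterols are skipped so the
    comparison always spans the nearest measurable pair. Flags are invariant
    to uniform rescaling of all rates.
    """
    flags: list[SegmentFlag] = []
    for branch, order in (("bloch", BLOCH_ORDER), ("kr", KR_ORDER)):
        present = [s for s in order if s in rates and rates[s] is not None]
        for up, down in zip(present, present[1:]):
            if rates[up] <= 0:
                continue
            ratio = rates[down] / rates[up]
            flags.append(SegmentFlag(up, down, float(ratio),
                                     flagged=ratio < threshold, branch=branch))
    # off-pathway branch: dihydrolanosterol fed from lanosterol
    if "lanosterol" in rates and "dihydrolanosterol" in rates \
            and rates["lanosterol"] > 0 and rates["dihydrolanosterol"] > 0:
        ratio = rates["dihydrolanosterol"] / rates["lanosterol"]
        flags.append(SegmentFlag("lanosterol", "dihydrolanosterol",
                                 float(ratio), flagged=True, branch="off-pathway"))
    return flags


@dataclass
class PathwayReport:
    """Per-tissue/condition pathway utilization summary."""

    condition: str
    rates: dict[str, float]
    bloch_fraction: float | None = None
    bloch_fraction_alt: float | None = None
    ln_lanosterol_rate: float | None = None
    flux_drops: list[SegmentFlag] = field(default_factory=list)
    undefined_reason: str = ""

    @classmethod
    def from_rates(cls, condition: str, rates: dict[str, float],
                   registry: SterolRegistry,
                   threshold: float = FLUX_DROP_THRESHOLD) -> "PathwayReport":
        rep = cls(condition=condition, rates=dict(rates))
        des = rates.get("desmosterol")
        dhc = rates.get("7-dehydrocholesterol")
        lan = rates.get("lanosterol")
        if des is None or dhc is None:
            rep.undefined_reason = "terminal rate unmeasured"
        elif des + dhc <= 0:
            rep.undefined_reason = "terminal rates are zero"
        else:
            rep.bloch_fraction = bloch_fraction(des, dhc)
        if lan is not None and lan > 0:
            if des is not None:
                rep.bloch_fraction_alt = bloch_fraction_alt(des, lan)
            rep.ln_lanosterol_rate = float(np.log(lan))
        rep.flux_drops = flux_drop_diagnostics(rates, registry, threshold)
        return rep


def utilization_vs_logflux(reports: list[PathwayReport]) -> dict:
    """Pair fractional Bloch utilization with ln(lanosterol synthesis rate).

    Returns a dict with the paired table, descriptive least-squares
    slope/intercept, the Pearson correlation, and per-row residual ranks
    (largest absolute residual first) for outlier inspection.
    """
    if len(reports) < 2:
        raise InvalidInputError("need >= 2 reports")
    rows = []
    for rep in reports:
        if rep.bloch_fraction is None:
            warnings.warn(f"{rep.condition}: bloch fraction undefined, dropped")
            continue
        if rep.ln_lanosterol_rate is None:
            warnings.warn(f"{rep.condition}: non-positive lanosterol rate, dropped")
            continue
        rows.append((rep.condition, rep.ln_lanosterol_rate, rep.bloch_fraction))
    table = pd.DataFrame(rows, columns=["condition", "ln_lanosterol_rate",
                                        "bloch_fraction"])
    out = {"table": table, "slope": None, "intercept": None, "correlation": None}
    if len(table) < 2:
        return out
    x = table["ln_lanosterol_rate"].to_numpy()
    y = table["bloch_fraction"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in utilization-vs-logflux inputs")
        return out
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    table["residual"] = resid
    table["residual_rank"] = pd.Series(np.abs(resid)).rank(ascending=False).astype(int)
    out.update(slope=float(slope), intercept=float(intercept),
               correlation=float(np.corrcoef(x, y)[0, 1]))
    return out


def tracer_conversion_summary(tracer_table: pd.DataFrame, protein: float,
                              is_area: float) -> dict[str, float]:
    """Normalize single-timepoint tracer (d5/d6) intensities to total protein
    and the internal standard.

    ``tracer_table`` needs columns sterol and intensity (labeled-isotopomer
    signal). Returns per-sterol normalized levels; ratios between conditions
    are then directly comparable.
    """
    if protein <= 0 or is_area <= 0:
        raise QuantitationError("protein amount and IS area must be > 0")
    required = {"sterol", "intensity"}
    if not required.issubset(tracer_table.columns):
        raise InvalidInputError(f"tracer table needs columns {sorted(required)}")
    grouped = tracer_table.groupby("sterol")["intensity"].sum()
    return {str(s): float(v) / (protein * is_area) for s, v in grouped.items()}
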