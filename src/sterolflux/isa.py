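"""Isotopomer deconvolution: fraction of newly synthesized molecules (g).

A measured M+0 fraction is a mixture of two reference states: molecules made
before labeling began (natural M+0 fraction, M0_n) and molecules made
entirely in labeled water (fully-labeled fraction, M0_t):

    M0_m = g * M0_t + (1 - g) * M0_n

solved linearly for g, the fraction of the pool synthesized since labeling
began. The same two-point deconvolution works for any isotopomer peak whose
natural and fully-labeled abundances differ enough to be informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, DegenerateSpectrumError,
                     PeakUninformativeError, UnidentifiableModelError)
from .isotopes import (CARBON_ONLY_ABUNDANCES, FragmentFormula,
                       IsotopeAbundanceTable, MassShiftSpectrum,
                       asymptotic_m0, natural_m0)
from .registry import SterolRegistry

logger = logging.getLogger(__name__)

__all__ = ["LabelModel", "TurnoverSeries", "m0_fraction", "fraction_new_from_m0",
           "fraction_new_from_peak", "build_turnover_series"]

#: Minimum |labeled - natural| for a peak to support deconvolution on its own.
IDENTIFIABILITY_FLOOR = 0.02


@dataclass(frozen=True)
class LabelModel:
    """Per-sterol label model: enrichment p, sites N and the two windowed
    M+0 reference fractions that bracket the measurement."""

    p: float
    N: int
    M0_n: float
    M0_t: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 0.5):
            raise ConfigurationError(f"enrichment p must be in [0, 0.5], got {self.p}")
        if self.p > 0 and self.N > 0 and not (0.0 < self.M0_t < self.M0_n <= 1.0):
            raise ConfigurationError(
                f"expected 0 < M0_t < M0_n <= 1, got M0_t={self.M0_t}, M0_n={self.M0_n}")

    @classmethod
    def from_parameters(cls, formula: FragmentFormula, n_sites: int, p: float,
                        window: int = 3,
                        abundances: IsotopeAbundanceTable = CARBON_ONLY_ABUNDANCES,
                        measurable_shifts: tuple[int, ...] | None = None,
                        ) -> "LabelModel":
        """Build the model from first principles (forward isotopomer model)."""
        return cls(
            p=p, N=int(n_sites),
            M0_n=natural_m0(formula, window, abundances, measurable_shifts),
            M0_t=asymptotic_m0(formula, n_sites, p, window, abundances,
                               measurable_shifts),
        )


@dataclass
class TurnoverSeries:
    """(time, g) observations for one sterol under one condition.

    ``observations`` is a DataFrame with columns time_hr, g, replicate.
    Noise can push individual g outside [0, 1]; such points are flagged in
    ``out_of_range`` but retained (clipping would bias the kinetic fit).
    """

    sterol: str
    condition: str
    observations: pd.DataFrame
    out_of_range: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.observations) == 0:
            raise ConfigurationError("turnover series must be non-empty")
        if (self.observations["time_hr"] < 0).any():
            raise ConfigurationError("times must be >= 0")
        g = self.observations["g"]
        self.out_of_range = int(((g < 0) | (g > 1)).sum())

    @property
    def times(self) -> np.ndarray:
        return self.observations["time_hr"].to_numpy(dtype=float)

    @property
    def g(self) -> np.ndarray:
        return self.observations["g"].to_numpy(dtype=float)

    def n_distinct_times(self) -> int:
        return self.observations["time_hr"].nunique()


def m0_fraction(measured_spectrum: MassShiftSpectrum) -> float:
    """M+0 intensity divided by the summed intensity of all measured peaks."""
    arr = measured_spectrum.as_array()
    total = arr.sum()
    if total <= 0:
        raise DegenerateSpectrumError("measured spectrum has zero total intensity")
    return float(arr[0] / total)


def fraction_new_from_m0(m0_m: float, model: LabelModel) -> float:
    """Linear deconvolution g = (M0_m - M0_n) / (M0_t - M0_n)."""
    denom = model.M0_t - model.M0_n
    if denom == 0:
        raise UnidentifiableModelError(
            "M0_t equals M0_n; labeling does not move the M+0 fraction")
    return (m0_m - model.M0_n) / denom


def fraction_new_from_peak(peak_index: int, measured: float, natural: float,
                           labeled: float,
                           floor: float = IDENTIFIABILITY_FLOOR) -> float:
    """Per-peak deconvolution: any isotopomer peak i with distinct natural and
    fully-labeled abundances yields the same g as the M+0 peak."""
    if abs(labeled - natural) < floor:
        raise PeakUninformativeError(
            f"peak M+{peak_index}: |labeled - natural| = "
            f"{abs(labeled - natural):.4f} below identifiability floor {floor}")
    return (measured - natural) / (labeled - natural)


def build_turnover_series(peak_table, models: dict[str, LabelModel],
                          registry: SterolRegistry,
                          window: int = 3) -> list[TurnoverSeries]:
    """Deconvolute a validated peak table into per-(sterol, condition) series.

    Masked/isobaric peaks are excluded per the registry before the M+0
    fraction is computed; fully masked sterols are dropped with a warning.
    Each replicate keeps its own g value (replicates are fitted jointly
    downstream, not averaged here).
    """
    peaks = peak_table.peaks
    series: list[TurnoverSeries] = []
    for (sterol, condition), grp in peaks.groupby(["sterol", "condition"], sort=True):
        if sterol not in registry:
            raise ConfigurationError(f"sterol {sterol!r} missing from registry")
        sdef = registry[sterol]
        if sdef.pathway == "standard":
            continue
        if not sdef.measurable:
            logger.warning("sterol %s excluded: %s", sterol,
                           sdef.masking_note or "not measurable")
            continue
        if sterol not in models:
            raise ConfigurationError(f"no label model for sterol {sterol!r}")
        model = models[sterol]
        shifts = set(registry.shifts_for(sterol, window))
        rows = []
        for (t, rep), obs in grp.groupby(["time_hr", "replicate"]):
            obs = obs[obs["mass_shift"].isin(shifts)]
            by_shift = obs.set_index("mass_shift")["intensity"]
            if 0 not in by_shift.index or by_shift.sum() <= 0:
                logger.warning("sterol %s t=%s rep=%s skipped: no M+0 peak",
                               sterol, t, rep)
                continue
            m0_m = float(by_shift.loc[0] / by_shift.sum())
            rows.append((float(t), fraction_new_from_m0(m0_m, model), rep))
        if rows:
            series.append(TurnoverSeries(
                sterol=str(sterol), condition=str(condition),
                observations=pd.DataFrame(rows, columns=["time_hr", "g", "replicate"])))
    return series
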