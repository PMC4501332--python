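"""Synthetic LC-MS/MS peak tables with known ground truth.

The generator is the forward model of the analysis run in reverse: each
sterol's labeled fraction follows g(t) = g_inf (1 - exp(-k t)); its windowed
isotopomer spectrum is the g-weighted mixture of the natural and
fully-labeled model spectra (each normalized over the sterol's measurable
shifts, so isobaric masking is applied at generation time exactly as the
analysis applies it at deconvolution time); absolute intensities are scaled
so that internal-standard quantitation recovers the ground-truth
concentration; multiplicative log-normal noise (unit mean) perturbs each
peak. Noise substreams are derived per (sterol, time, replicate), so adding
a sterol to a scenario does not perturb the noise of the others.

Tissue presets encode the qualitative flux architecture observed across
mouse tissues: testes run the Bloch branch with a two-thirds diversion of
t-MAS, the liver splits terminal flux evenly and shunts ~7.5% of lanosterol
to dihydrolanosterol, the preputial gland and skin are dominated by the
modified Kandutsch-Russell branch, the adrenal converts lanosterol
quantitatively to desmosterol, and the brain turns over slowly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError
from .isotopes import (CARBON_ONLY_ABUNDANCES, IsotopeAbundanceTable,
                       incorporation_spectrum, convolve, natural_spectrum)
from .registry import SterolRegistry, default_registry

__all__ = ["SterolTruth", "SimulationTruth", "TracerScenario", "PeakTable",
           "CELL_TIMES_HR", "MOUSE_TIMES_HR", "tissue_preset", "PRESET_NAMES",
           "simulate_timecourse", "simulate_tracer_experiment",
           "write_peak_table", "read_peak_table"]

#: Cell-culture harvest schedule (hours).
CELL_TIMES_HR = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0)
#: Mouse sacrifice schedule (hours); 0 covers the unlabeled baseline animals.
MOUSE_TIMES_HR = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 18.0, 24.0,
                  48.0, 72.0, 120.0, 168.0)

PEAK_COLUMNS = ["sample_id", "condition", "sterol", "time_hr", "replicate",
                "mass_shift", "intensity"]
SAMPLE_COLUMNS = ["sample_id", "condition", "time_hr", "replicate",
                  "is_amount_ng", "normalizer_kind", "normalizer_amount"]


@dataclass(frozen=True)
class SterolTruth:
    """Ground truth for one sterol: label sites, kinetics, pool size."""

    N: int                    # deuterium incorporation sites
    k: float                  # turnover rate constant, per hour
    g_inf: float              # asymptotic labeled fraction
    concentration: float      # ng per unit normalizer

    def __post_init__(self) -> None:
        if self.k < 0 or self.concentration < 0:
            raise InvalidInputError("k and concentration must be >= 0")
        if not (0.0 <= self.g_inf <= 1.0):
            raise InvalidInputError("g_inf must be in [0, 1]")

    @property
    def rate_per_hr(self) -> float:
        return self.k * self.concentration

    @property
    def rate_per_day(self) -> float:
        return self.rate_per_hr * 24.0


@dataclass(frozen=True)
class SimulationTruth:
    """Complete ground truth for one simulated labeling experiment."""

    condition: str
    p: float                                  # water-pool D2O enrichment
    sterols: dict[str, SterolTruth]
    times_hr: tuple[float, ...] = CELL_TIMES_HR
    replicates: int = 3
    noise_cv: float = 0.02
    masking: bool = True
    seed: int = 0
    window: int = 3
    is_amount_ng: float = 20.0
    is_area: float = 1.0e5                    # IS counts for is_amount_ng
    normalizer_kind: str = "protein_ug"
    normalizer_amount: float = 100.0
    abundances: IsotopeAbundanceTable = CARBON_ONLY_ABUNDANCES

    def __post_init__(self) -> None:
        times = tuple(self.times_hr)
        if list(times) != sorted(times) or times[0] != 0.0:
            raise InvalidInputError("times must be sorted and include 0")
        if not (0.0 <= self.p <= 0.5):
            raise InvalidInputError("p must be in [0, 0.5]")
        if self.noise_cv < 0:
            raise InvalidInputError("noise_cv must be >= 0")

    def bloch_fraction_truth(self) -> float | None:
        des = self.sterols.get("desmosterol")
        dhc = self.sterols.get("7-dehydrocholesterol")
        if des is None or dhc is None:
            return None
        total = des.rate_per_hr + dhc.rate_per_hr
        return des.rate_per_hr / total if total > 0 else None


@dataclass
class PeakTable:
    """Long-format peak intensities plus per-sample metadata."""

    peaks: pd.DataFrame
    samples: pd.DataFrame

    def is_area_for(self, sample_id: str) -> float:
        sel = self.peaks[(self.peaks["sample_id"] == sample_id)
                         & (self.peaks["sterol"] == "d6-sitosterol")]
        return float(sel["intensity"].sum())


# --------------------------------------------------------------------------
# Tissue presets
# --------------------------------------------------------------------------

def _truths(entries: dict) -> dict[str, SterolTruth]:
    """entries: name -> (N, rate_ng_per_day, g_inf, conc).  k is derived as
    rate / (24 * conc), making rate ratios (the pathway architecture) exact
    by construction."""
    out = {}
    for name, (n, rate_day, gi, conc) in entries.items():
        out[name] = SterolTruth(N=n, k=rate_day / (24.0 * conc),
                                g_inf=gi, concentration=conc)
    return out


# Per-sterol (N, synthesis rate ng/normalizer/day, g_inf, concentration).
# Rate architecture encodes each tissue's pathway split; N values span the
# plausible 20-28 range. Concentrations are chosen so that every rate
# constant is fast enough for the pool to turn over within the labeling
# window (the design assumption behind asymptote-based calibration).
_PRESETS: dict[str, dict] = {
    # Bloch-dominated; two-thirds of t-MAS diverted before zymosterol;
    # terminal split 9.7 : 0.3 -> bloch fraction 0.97 by construction.
    "testes": dict(p=0.048, times=MOUSE_TIMES_HR, normalizer=("tissue_mg", 50.0),
                   entries={
        "lanosterol":           (22, 30.0, 1.0, 10.0),
        "ff-MAS":               (23, 30.0, 1.0, 8.0),
        "t-MAS":                (23, 30.0, 1.0, 12.0),
        "zymosterol":           (24, 10.0, 1.0, 6.0),
        "dehydrodesmosterol":   (24, 10.0, 1.0, 5.0),
        "desmosterol":          (24, 9.7,  1.0, 8.0),
        "7-dehydrocholesterol": (25, 0.3,  1.0, 0.25),
    }),
    # Even terminal split (bloch fraction exactly 0.5); dihydrolanosterol
    # branch at 7.5% of lanosterol flux.
    "liver": dict(p=0.048, times=MOUSE_TIMES_HR, normalizer=("tissue_mg", 50.0),
                  entries={
        "lanosterol":           (22, 40.0, 1.0, 5.0),
        "ff-MAS":               (23, 40.0, 1.0, 8.0),
        "t-MAS":                (23, 40.0, 1.0, 10.0),
        "zymosterol":           (24, 40.0, 1.0, 8.0),
        "dehydrodesmosterol":   (24, 40.0, 1.0, 6.0),
        "desmosterol":          (24, 20.0, 1.0, 10.0),
        "7-dehydrocholesterol": (25, 20.0, 1.0, 8.0),
        "dihydrolanosterol":    (22, 3.0,  1.0, 2.0),
    }),
    # MK-R dominated: terminal split 0.8 : 9.2 -> bloch fraction 0.08.
    "preputial": dict(p=0.048, times=MOUSE_TIMES_HR, normalizer=("tissue_mg", 20.0),
                      entries={
        "lanosterol":           (22, 10.0, 1.0, 2.0),
        "ff-MAS":               (23, 10.0, 1.0, 4.0),
        "t-MAS":                (23, 10.0, 1.0, 6.0),
        "zymosterol":           (24, 10.0, 1.0, 3.0),
        "dehydrodesmosterol":   (24, 0.8,  1.0, 0.8),
        "desmosterol":          (24, 0.8,  1.0, 0.8),
        "7-dehydrocholesterol": (25, 9.2,  1.0, 4.0),
    }),
    # MK-R dominated skin with measurable dihydro-t-MAS synthesis.
    "skin": dict(p=0.048, times=MOUSE_TIMES_HR, normalizer=("tissue_mg", 50.0),
                 entries={
        "lanosterol":           (22, 10.0, 1.0, 4.0),
        "ff-MAS":               (23, 10.0, 1.0, 5.0),
        "t-MAS":                (23, 10.0, 1.0, 6.0),
        "zymosterol":           (24, 10.0, 1.0, 4.0),
        "dehydrodesmosterol":   (24, 1.5,  1.0, 1.25),
        "desmosterol":          (24, 1.5,  1.0, 1.25),
        "7-dehydrocholesterol": (25, 8.5,  1.0, 4.0),
        "dihydro-t-MAS":        (24, 0.5,  1.0, 0.7),
    }),
    # Bloch only; lanosterol converted quantitatively to desmosterol.
    "adrenal": dict(p=0.048, times=MOUSE_TIMES_HR, normalizer=("tissue_mg", 10.0),
                    entries={
        "lanosterol":           (22, 8.0, 1.0, 2.0),
        "ff-MAS":               (23, 8.0, 1.0, 3.0),
        "t-MAS":                (23, 8.0, 1.0, 4.0),
        "zymosterol":           (24, 8.0, 1.0, 3.0),
        "dehydrodesmosterol":   (24, 8.0, 1.0, 2.5),
        "desmosterol":          (24, 7.8, 1.0, 5.0),
        "7-dehydrocholesterol": (25, 0.2, 1.0, 0.17),
    }),
    # Slow absolute turnover, MK-R dominated.
    "brain": dict(p=0.048, times=MOUSE_TIMES_HR, normalizer=("tissue_mg", 50.0),
                  entries={
        "lanosterol":           (22, 0.5, 1.0, 1.0),
        "zymosterol":           (24, 0.5, 1.0, 0.85),
        "dehydrodesmosterol":   (24, 0.1, 1.0, 0.2),
        "desmosterol":          (24, 0.1, 1.0, 0.2),
        "7-dehydrocholesterol": (25, 0.4, 1.0, 0.67),
    }),
    # Cultured fibroblasts (MK-R heavy) on the cell-culture schedule.
    "fibroblast": dict(p=0.05, times=CELL_TIMES_HR, normalizer=("protein_ug", 100.0),
                       entries={
        "lanosterol":           (22, 4.8,  1.0, 0.5),
        "ff-MAS":               (23, 4.3,  1.0, 0.6),
        "t-MAS":                (23, 4.2,  1.0, 0.7),
        "zymosterol":           (24, 3.6,  1.0, 0.5),
        "dehydrodesmosterol":   (24, 0.58, 1.0, 0.2),
        "desmosterol":          (24, 0.6,  1.0, 0.2),
        "7-dehydrocholesterol": (25, 3.0,  1.0, 0.5),
    }),
    # Cultured adrenal line (Bloch heavy) on the cell-culture schedule.
    "adrenal-cell": dict(p=0.05, times=CELL_TIMES_HR,
                         normalizer=("protein_ug", 100.0), entries={
        "lanosterol":           (22, 4.8,  1.0, 0.5),
        "ff-MAS":               (23, 4.2,  1.0, 0.5),
        "t-MAS":                (23, 4.3,  1.0, 0.6),
        "zymosterol":           (24, 4.2,  1.0, 0.5),
        "dehydrodesmosterol":   (24, 3.6,  1.0, 0.5),
        "desmosterol":          (24, 3.5,  1.0, 0.6),
        "7-dehydrocholesterol": (25, 0.07, 1.0, 0.03),
    }),
}

PRESET_NAMES = tuple(_PRESETS)


def tissue_preset(name: str, seed: int = 0, noise_cv: float = 0.02,
                  replicates: int = 3) -> SimulationTruth:
    """Named ground-truth scenario for one tissue or cell line."""
    if name not in _PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(_PRESETS)}")
    spec = _PRESETS[name]
    kind, amount = spec["normalizer"]
    return SimulationTruth(
        condition=name, p=spec["p"], sterols=_truths(spec["entries"]),
        times_hr=tuple(spec["times"]), replicates=replicates,
        noise_cv=noise_cv, seed=seed,
        normalizer_kind=kind, normalizer_amount=amount)


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def _substream(seed: int, sterol: str, time_hr: float, replicate: int
               ) -> np.random.Generator:
    """Deterministic per-(sterol, time, replicate) noise stream."""
    key = (int(seed) & 0x7FFFFFFF,
           zlib.crc32(sterol.encode("utf-8")),
           int(round(time_hr * 1000)),
           int(replicate))
    return np.random.default_rng(np.random.SeedSequence(key))


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise at coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _windowed_mixture(sdef, truth: SimulationTruth, st: SterolTruth,
                      g: float, shifts: tuple[int, ...]) -> np.ndarray:
    """g-weighted mixture of natural and fully-labeled spectra, each
    normalized over the sterol's measurable shifts."""
    internal = truth.window + 4 + st.N
    nat = natural_spectrum(sdef.formula, truth.abundances, max_shift=internal).as_array()
    inc = incorporation_spectrum(st.N, truth.p, max_shift=internal)
    lab = convolve(
        natural_spectrum(sdef.formula, truth.abundances, max_shift=internal),
        inc, max_shift=internal).as_array()
    idx = np.array(shifts)
    nat_w = nat[idx] / nat[idx].sum()
    lab_w = lab[idx] / lab[idx].sum()
    return g * lab_w + (1.0 - g) * nat_w


def simulate_timecourse(truth: SimulationTruth,
                        registry: SterolRegistry | None = None) -> PeakTable:
    """Generate a labeling time-course peak table from ground truth.

    Deterministic given (truth, seed); intensities are scaled so that
    internal-standard quantitation recovers each sterol's true concentration
    in expectation.
    """
    registry = registry or default_registry()
    for name in truth.sterols:
        if name not in registry:
            raise ConfigurationError(f"sterol {name!r} not in registry")

    peak_rows, sample_rows = [], []
    for t in truth.times_hr:
        for rep in range(1, truth.replicates + 1):
            sample_id = f"{truth.condition}_t{t:g}_r{rep}"
            sample_rows.append((sample_id, truth.condition, t, rep,
                                truth.is_amount_ng, truth.normalizer_kind,
                                truth.normalizer_amount))
            # internal standard: single M+0 peak
            rng = _substream(truth.seed, "d6-sitosterol", t, rep)
            is_int = truth.is_area * _lognormal_noise(rng, truth.noise_cv, 1)[0]
            peak_rows.append((sample_id, truth.condition, "d6-sitosterol",
                              t, rep, 0, is_int))
            for name, st in truth.sterols.items():
                sdef = registry[name]
                if not sdef.measurable:
                    continue
                if truth.masking:
                    shifts = registry.shifts_for(name, truth.window)
                else:
                    shifts = tuple(range(truth.window + 1))
                g = st.g_inf * (1.0 - np.exp(-st.k * t))
                mix = _windowed_mixture(sdef, truth, st, g, shifts)
                total_area = (st.concentration * truth.normalizer_amount
                              / truth.is_amount_ng * truth.is_area)
                rng = _substream(truth.seed, name, t, rep)
                noise = _lognormal_noise(rng, truth.noise_cv, len(shifts))
                for shift, frac, eps in zip(shifts, mix, noise):
                    peak_rows.append((sample_id, truth.condition, name, t, rep,
                                      shift, total_area * frac * eps))

    return PeakTable(
        peaks=pd.DataFrame(peak_rows, columns=PEAK_COLUMNS),
        samples=pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS))


# --------------------------------------------------------------------------
# Tracer experiments (pre-labeled d5/d6 sterols, single time point)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TracerScenario:
    """Single-timepoint tracer design: a d5/d6-labeled sterol is fed and its
    label distributes into downstream sterols per ``conversion``."""

    condition: str
    tracer_sterol: str
    tracer_shift: int                       # 5 or 6
    dose_signal: float                      # counts; 0 emulates vehicle
    conversion: dict[str, float] = field(default_factory=dict)
    protein: float = 100.0
    is_area: float = 1.0e5
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tracer_shift not in (5, 6):
            raise InvalidInputError("tracer mass shift must be 5 or 6")
        if any(f < 0 for f in self.conversion.values()) \
                or sum(self.conversion.values()) > 1.0 + 1e-12:
            raise InvalidInputError("conversion fractions must be >= 0 and sum <= 1")


def simulate_tracer_experiment(scenario: TracerScenario,
                               registry: SterolRegistry | None = None
                               ) -> pd.DataFrame:
    """Labeled-isotopomer intensities at the tracer's extended mass window.

    Returns a table with columns condition, sterol, mass_shift, intensity.
    The un-converted fraction of the dose remains in the tracer sterol;
    vehicle scenarios (dose_signal = 0) yield zero signal everywhere.
    """
    registry = registry or default_registry()
    for name in (scenario.tracer_sterol, *scenario.conversion):
        if name not in registry:
            raise ConfigurationError(f"sterol {name!r} not in registry")
    remaining = 1.0 - sum(scenario.conversion.values())
    rows = []
    targets = {scenario.tracer_sterol: remaining, **scenario.conversion}
    for name, frac in targets.items():
        rng = _substream(scenario.seed, name, 5.0, 0)
        eps = _lognormal_noise(rng, scenario.noise_cv, 1)[0]
        rows.append((scenario.condition, name, scenario.tracer_shift,
                     scenario.dose_signal * frac * eps))
    return pd.DataFrame(rows, columns=["condition", "sterol", "mass_shift",
                                       "intensity"])


# --------------------------------------------------------------------------
# Delimited-text I/O
# --------------------------------------------------------------------------

def _samples_path(path) -> str:
    p = str(path)
    return (p[:-4] if p.endswith(".csv") else p) + ".samples.csv"


def write_peak_table(table: PeakTable, path) -> None:
    """Write peaks to ``path`` and sample metadata to a sibling
    ``<stem>.samples.csv``; byte-deterministic for a given table."""
    table.peaks.to_csv(path, index=False)
    table.samples.to_csv(_samples_path(path), index=False)


def read_peak_table(path) -> PeakTable:
    """Read and validate a peak table written by :func:`write_peak_table`.

    Raises :class:`ConfigurationError` naming the offending column or row for
    missing columns, non-numeric intensities, or duplicate
    (sample, sterol, mass shift) entries.
    """
    peaks = pd.read_csv(path)
    missing = set(PEAK_COLUMNS) - set(peaks.columns)
    if missing:
        raise ConfigurationError(f"peak table missing columns: {sorted(missing)}")
    bad = pd.to_numeric(peaks["intensity"], errors="coerce").isna()
    if bad.any():
        rows = peaks.index[bad].tolist()[:5]
        raise ConfigurationError(f"non-numeric intensity at rows {rows}")
    peaks["intensity"] = pd.to_numeric(peaks["intensity"])
    dup = peaks.duplicated(subset=["sample_id", "sterol", "mass_shift"], keep=False)
    if dup.any():
        rows = peaks.index[dup].tolist()[:5]
        raise ConfigurationError(
            f"duplicate (sample, sterol, mass_shift) rows at {rows}")

    import os
    spath = _samples_path(path)
    if os.path.exists(spath):
        samples = pd.read_csv(spath)
        missing = set(SAMPLE_COLUMNS) - set(samples.columns)
        if missing:
            raise ConfigurationError(f"sample table missing columns: {sorted(missing)}")
    else:
        samples = (peaks[["sample_id", "condition", "time_hr", "replicate"]]
                   .drop_duplicates().reset_index(drop=True))
    return PeakTable(peaks=peaks, samples=samples)
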