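"""Theoretical isotopomer spectra for sterol fragment ions.

The LC-MS/MS assay monitors each sterol's fragment ion at its nominal m/z
(M+0) plus a short window of heavier isotopomers (M+1 ... M+3 by default).
Two processes populate that window:

* natural isotope abundance — every carbon has a ~1.1% chance of being 13C,
  every hydrogen a 0.015% chance of being 2H; the resulting nominal-mass-shift
  distribution is a convolution of per-element binomials (multiplied onto the
  shift axis by the isotope's mass increment, +2 for 18O);
* biosynthetic deuterium incorporation — a molecule synthesized while the
  water pool is enriched to fraction ``p`` of D2O acquires deuterium at N
  effective sites, giving a Binomial(N, p) mass-shift distribution.

A measured spectrum of a fully turned-over pool is the convolution of the
two, truncated to the acquisition window and renormalized. This module
implements those pieces exactly (polynomial convolution, no sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .errors import DegenerateSpectrumError, InvalidInputError

__all__ = [
    "IsotopeAbundanceTable",
    "FragmentFormula",
    "MassShiftSpectrum",
    "CARBON_ONLY_ABUNDANCES",
    "FULL_NATURAL_ABUNDANCES",
    "natural_spectrum",
    "incorporation_spectrum",
    "convolve",
    "truncate_normalize",
    "windowed_m0",
    "asymptotic_m0",
]

# Extra shifts carried internally before a final truncation, so that window
# truncation happens once, after all convolutions (bounds edge loss < 1e-6
# for realistic N <= 40, p <= 0.1).
_GUARD_SHIFTS = 4


@dataclass(frozen=True)
class IsotopeAbundanceTable:
    """Per-element heavy-isotope abundances.

    ``entries`` maps an element symbol to ``(heavy_fraction, mass_shift)``:
    the per-atom probability of carrying the heavy isotope and the nominal
    mass increment that isotope contributes (+1 for 13C and 2H, +2 for 18O).
    """

    entries: dict[str, tuple[float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sym, (frac, shift) in self.entries.items():
            if not (0.0 <= frac < 1.0):
                raise InvalidInputError(
                    f"heavy_fraction for {sym} must be in [0, 1), got {frac}"
                )
            if int(shift) != shift or shift < 1:
                raise InvalidInputError(
                    f"mass_shift for {sym} must be an integer >= 1, got {shift}"
                )

    def heavy_fraction(self, symbol: str) -> float:
        return self.entries.get(symbol, (0.0, 1))[0]

    def mass_shift(self, symbol: str) -> int:
        return self.entries.get(symbol, (0.0, 1))[1]


#: Carbon-dominant preset: only 13C contributes. Reproduces the printed
#: natural-abundance percentages for sterol fragment ions (the fragments are
#: dehydrated, so 18O is absent, and 2H at 0.015% shifts M+0 by < 0.5%).
CARBON_ONLY_ABUNDANCES = IsotopeAbundanceTable({"C": (0.011, 1)})

#: Full natural abundances: 13C 1.1%, 2H 0.015%, 18O 0.205%.
FULL_NATURAL_ABUNDANCES = IsotopeAbundanceTable(
    {"C": (0.011, 1), "H": (0.00015, 1), "O": (0.00205, 2)}
)


@dataclass(frozen=True)
class FragmentFormula:
    """Elemental composition of a detected fragment ion (C/H/O only)."""

    carbon_count: int
    hydrogen_count: int = 0
    oxygen_count: int = 0

    def __post_init__(self) -> None:
        for name in ("carbon_count", "hydrogen_count", "oxygen_count"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise InvalidInputError(f"{name} must be a non-negative integer, got {v}")
        if self.total_atoms == 0:
            raise InvalidInputError("fragment formula must contain at least one atom")

    @property
    def total_atoms(self) -> int:
        return self.carbon_count + self.hydrogen_count + self.oxygen_count

    def atom_counts(self) -> dict[str, int]:
        return {"C": self.carbon_count, "H": self.hydrogen_count, "O": self.oxygen_count}


@dataclass(frozen=True)
class MassShiftSpectrum:
    """Fractional abundances of isotopomer peaks indexed by mass shift 0..K.

    ``fractions[i]`` is the abundance of the M+i peak. When ``normalized`` the
    fractions sum to 1; otherwise mass truncated away by the window remains
    unaccounted for (the spectrum sums to < 1).
    """

    fractions: tuple[float, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.fractions) < 2:
            raise InvalidInputError("a spectrum needs at least peaks M+0 and M+1")
        arr = np.asarray(self.fractions, dtype=float)
        if np.any(arr < -1e-15):
            raise InvalidInputError("spectrum fractions must be non-negative")
        if self.normalized and abs(arr.sum() - 1.0) > 1e-9:
            raise InvalidInputError(
                f"normalized spectrum must sum to 1, got {arr.sum():.12f}"
            )

    @property
    def window_size(self) -> int:
        """Number of peaks beyond M+0 (K in M+0..M+K)."""
        return len(self.fractions) - 1

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    @property
    def m0(self) -> float:
        return self.fractions[0]


def _from_array(arr: np.ndarray, normalized: bool = False) -> MassShiftSpectrum:
    arr = np.clip(np.asarray(arr, dtype=float), 0.0, None)
    return MassShiftSpectrum(tuple(arr.tolist()), normalized=normalized)


def _element_shift_pmf(n_atoms: int, heavy_fraction: float, mass_shift: int,
                       max_shift: int) -> np.ndarray:
    """Mass-shift pmf contributed by one element: Binomial(n, q) placed on a
    shift axis stretched by the isotope's mass increment."""
    n_heavy_max = min(n_atoms, max_shift // mass_shift)
    pmf = np.zeros(max_shift + 1)
    ks = np.arange(n_heavy_max + 1)
    pmf[ks * mass_shift] = binom.pmf(ks, n_atoms, heavy_fraction)
    return pmf


def natural_spectrum(formula: FragmentFormula,
                     abundances: IsotopeAbundanceTable = FULL_NATURAL_ABUNDANCES,
                     max_shift: int = 12) -> MassShiftSpectrum:
    """Natural-abundance isotopomer distribution of a fragment ion.

    Exact polynomial convolution of per-element binomial shift distributions,
    truncated at ``max_shift``. The truncated tail is *not* renormalized: the
    returned fractions are absolute probabilities and sum to < 1 by at most
    the (tiny) truncated mass.
    """
    if max_shift < 1:
        raise InvalidInputError(f"max_shift must be >= 1, got {max_shift}")
    result = np.zeros(max_shift + 1)
    result[0] = 1.0
    for sym, n_atoms in formula.atom_counts().items():
        if n_atoms == 0:
            continue
        q = abundances.heavy_fraction(sym)
        if q == 0.0:
            continue
        pmf = _element_shift_pmf(n_atoms, q, abundances.mass_shift(sym), max_shift)
        result = np.convolve(result, pmf)[: max_shift + 1]
    return _from_array(result)


def incorporation_spectrum(n_sites: int, p: float, max_shift: int = 12) -> MassShiftSpectrum:
    """Binomial(N, p) deuterium-incorporation spectrum, truncated at max_shift."""
    if int(n_sites) != n_sites or n_sites < 0:
        raise InvalidInputError(f"n_sites must be a non-negative integer, got {n_sites}")
    if not (0.0 <= p < 1.0):
        raise InvalidInputError(f"enrichment p must be in [0, 1), got {p}")
    if max_shift < 1:
        raise InvalidInputError(f"max_shift must be >= 1, got {max_shift}")
    shifts = np.arange(max_shift + 1)
    return _from_array(binom.pmf(shifts, int(n_sites), p))


def convolve(a: MassShiftSpectrum, b: MassShiftSpectrum,
             max_shift: int | None = None) -> MassShiftSpectrum:
    """Discrete convolution of two mass-shift spectra, truncated at max_shift.

    Models independent superposition of two shift-generating processes
    (e.g. natural abundance and label incorporation). Commutative;
    (1, 0, ...) is the identity.
    """
    fa, fb = a.as_array(), b.as_array()
    full = np.convolve(fa, fb)
    if max_shift is None:
        max_shift = len(full) - 1
    out = full[: max_shift + 1]
    if len(out) < max_shift + 1:
        out = np.pad(out, (0, max_shift + 1 - len(out)))
    return _from_array(out)


def truncate_normalize(spectrum: MassShiftSpectrum, window: int) -> MassShiftSpectrum:
    """Restrict to the acquisition window M+0..M+window and renormalize.

    This is the operation the assay itself performs: fractional abundances
    are computed over the measurable isotopomers only.
    """
    if window < 1:
        raise InvalidInputError(f"window must be >= 1, got {window}")
    arr = spectrum.as_array()[: window + 1]
    if len(arr) < window + 1:
        arr = np.pad(arr, (0, window + 1 - len(arr)))
    total = arr.sum()
    if total <= 0:
        raise DegenerateSpectrumError("all retained peaks are zero")
    return _from_array(arr / total, normalized=True)


def windowed_m0(spectrum: MassShiftSpectrum, shifts: tuple[int, ...]) -> float:
    """M+0 fraction over an arbitrary set of measurable shifts.

    Generalizes :func:`truncate_normalize` to sterols whose window has holes
    (isobaric masking can censor M+2/M+3 while M+0/M+1 stay measurable).
    ``shifts`` must include 0.
    """
    if 0 not in shifts:
        raise InvalidInputError("measurable shifts must include M+0")
    arr = spectrum.as_array()
    total = sum(arr[s] for s in shifts if s < len(arr))
    if total <= 0:
        raise DegenerateSpectrumError("no signal in measurable shifts")
    return float(arr[0] / total)


def labeled_spectrum(formula: FragmentFormula, n_sites: int, p: float,
                     window: int = 3,
                     abundances: IsotopeAbundanceTable = CARBON_ONLY_ABUNDANCES,
                     ) -> MassShiftSpectrum:
    """Windowed model spectrum of a fully turned-over pool: natural abundance
    convolved with Binomial(N, p), truncated to the window and renormalized."""
    internal = window + _GUARD_SHIFTS + int(n_sites)
    nat = natural_spectrum(formula, abundances, max_shift=internal)
    inc = incorporation_spectrum(n_sites, p, max_shift=internal)
    return truncate_normalize(convolve(nat, inc, max_shift=internal), window)


def asymptotic_m0(formula: FragmentFormula, n_sites: int, p: float,
                  window: int = 3,
                  abundances: IsotopeAbundanceTable = CARBON_ONLY_ABUNDANCES,
                  measurable_shifts: tuple[int, ...] | None = None) -> float:
    """Model M0_t: windowed M+0 fraction of the fully-labeled spectrum.

    Strictly decreasing in ``p`` (for N > 0) and in ``N`` (for p > 0).
    ``measurable_shifts`` restricts the normalizing window for sterols with
    masked peaks; default is the contiguous window 0..window.
    """
    internal = window + _GUARD_SHIFTS + int(n_sites)
    nat = natural_spectrum(formula, abundances, max_shift=internal)
    inc = incorporation_spectrum(n_sites, p, max_shift=internal)
    full = convolve(nat, inc, max_shift=internal)
    if measurable_shifts is None:
        measurable_shifts = tuple(range(window + 1))
    return windowed_m0(full, measurable_shifts)


def natural_m0(formula: FragmentFormula, window: int = 3,
               abundances: IsotopeAbundanceTable = CARBON_ONLY_ABUNDANCES,
               measurable_shifts: tuple[int, ...] | None = None) -> float:
    """Model M0_n: windowed M+0 fraction of the natural-abundance spectrum."""
    return asymptotic_m0(formula, 0, 0.0, window, abundances, measurable_shifts)
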