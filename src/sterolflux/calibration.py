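"""Label-model calibration: M0_n from unlabeled spectra, N by regression
against the asymptotic spectrum, and joint (N, p) estimation across tissues.

In cell culture the water enrichment p is set by the experimenter (5% D2O,
p = 0.05) and only the per-sterol site count N must be estimated, by matching
the observed asymptotic M+0 fraction to the forward isotopomer model. In
mice, body-water enrichment is not known exactly, so a single global p and
per-sterol/tissue N values are estimated jointly by alternating
minimization of the root-mean-square misfit across all tissues.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import gammaln
from scipy.stats import binom

from .errors import ConvergenceError, InvalidInputError
from .isotopes import (CARBON_ONLY_ABUNDANCES, FragmentFormula,
                       IsotopeAbundanceTable, MassShiftSpectrum, convolve,
                       natural_m0, natural_spectrum, windowed_m0)

logger = logging.getLogger(__name__)

__all__ = ["AsymptoticObservation", "m0n_from_unlabeled", "estimate_N",
           "joint_estimate_Np", "JointCalibration"]

_GUARD = 4


@dataclass(frozen=True)
class AsymptoticObservation:
    """Observed asymptotic (fully-turned-over) M+0 fraction for one sterol in
    one tissue or condition."""

    sterol: str
    tissue: str
    m0_t: float
    spectrum: MassShiftSpectrum | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.m0_t < 1.0):
            raise InvalidInputError(f"asymptotic M+0 must be in (0,1), got {self.m0_t}")


def m0n_from_unlabeled(spectra: list[MassShiftSpectrum],
                       formula: FragmentFormula | None = None,
                       window: int = 3,
                       abundances: IsotopeAbundanceTable = CARBON_ONLY_ABUNDANCES,
                       ) -> tuple[float, float | None]:
    """Mean windowed M+0 fraction of unlabeled spectra.

    Returns ``(m0_n, deviation)`` where ``deviation`` is the difference from
    the theoretical natural-abundance prediction when a formula is given
    (None otherwise) — a sanity check that observed unlabeled samples agree
    with the natural abundance calculator.
    """
    if not spectra:
        raise InvalidInputError("need at least one unlabeled spectrum")
    shifts = tuple(range(window + 1))
    vals = [windowed_m0(s, shifts) for s in spectra]
    m0n = float(np.mean(vals))
    deviation = None
    if formula is not None:
        deviation = m0n - natural_m0(formula, window, abundances)
    return m0n, deviation


def _continuous_binomial_pmf(k: np.ndarray, n: float, p: float) -> np.ndarray:
    """Binomial pmf with a continuous number of trials, via gamma functions.

    Used only inside the continuous-N regression; for integer n it equals the
    ordinary binomial pmf.
    """
    k = np.asarray(k, dtype=float)
    with np.errstate(divide="ignore"):
        logpmf = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
                  + k * np.log(p) + (n - k) * np.log1p(-p))
    out = np.exp(logpmf)
    out[k > n] = 0.0
    return out


def _model_m0(formula: FragmentFormula, n: float, p: float, window: int,
              abundances: IsotopeAbundanceTable,
              measurable_shifts: tuple[int, ...] | None) -> float:
    """Windowed asymptotic M+0 for possibly non-integer N."""
    internal = window + _GUARD + int(np.ceil(n))
    nat = natural_spectrum(formula, abundances, max_shift=internal)
    if p == 0 or n == 0:
        full = nat
    else:
        inc = _continuous_binomial_pmf(np.arange(internal + 1), n, p)
        full = convolve(nat, MassShiftSpectrum(tuple(inc)), max_shift=internal)
    shifts = measurable_shifts or tuple(range(window + 1))
    return windowed_m0(full, shifts)


def estimate_N(obs: AsymptoticObservation, p: float, formula: FragmentFormula,
               window: int = 3, search_range: tuple[int, int] = (5, 40),
               abundances: IsotopeAbundanceTable = CARBON_ONLY_ABUNDANCES,
               measurable_shifts: tuple[int, ...] | None = None) -> int:
    """Estimate the deuterium site count N from one asymptotic M+0 value.

    The model M+0 is strictly decreasing in N at fixed p > 0, so the
    least-squares minimizer over continuous N is the root of
    model(N) - observed; it is found by bisection and rounded to the nearest
    integer (ties round up). If the observation lies outside the range the
    model can reach, the nearest boundary is returned with a warning.
    """
    if p <= 0:
        raise InvalidInputError("estimate_N requires p > 0")
    lo, hi = search_range
    f = lambda n: _model_m0(formula, n, p, window, abundances,
                            measurable_shifts) - obs.m0_t
    f_lo, f_hi = f(lo), f(hi)
    if f_lo <= 0:          # observed M0 >= model at smallest N
        warnings.warn(f"{obs.sterol}/{obs.tissue}: N estimate at lower boundary {lo}")
        return lo
    if f_hi >= 0:
        warnings.warn(f"{obs.sterol}/{obs.tissue}: N estimate at upper boundary {hi}")
        return hi
    n_star = brentq(f, lo, hi, xtol=1e-10)
    return int(np.floor(n_star + 0.5))   # ties (x.5) round up


@dataclass
class JointCalibration:
    """Result of the alternating (N, p) regression."""

    p: float
    N: dict[str, int]                   # sterol -> N (shared across tissues)
    rms: float
    n_iterations: int
    degenerate: bool = False


_NAT_CACHE: dict = {}


def _nat_lowtri(formula: FragmentFormula, window: int,
                abundances: IsotopeAbundanceTable) -> np.ndarray:
    """Lower-triangular convolution matrix of the natural spectrum's first
    window+1 terms. Exact: peak s of the convolved spectrum only involves
    terms 0..s of each factor."""
    key = (formula, window, id(abundances))
    if key not in _NAT_CACHE:
        nat = natural_spectrum(formula, abundances, max_shift=window).as_array()
        T = np.zeros((window + 1, window + 1))
        for j in range(window + 1):
            T[j, j:] = nat[: window + 1 - j]
        _NAT_CACHE[key] = T
    return _NAT_CACHE[key]


def _m0_table(formula: FragmentFormula, grid: np.ndarray, p: float,
              window: int, abundances: IsotopeAbundanceTable,
              shifts: tuple[int, ...] | None) -> np.ndarray:
    """Windowed asymptotic M+0 over an integer-N grid (vectorized over N)."""
    T = _nat_lowtri(formula, window, abundances)
    ks = np.arange(window + 1)
    inc = binom.pmf(ks[None, :], grid[:, None], p)      # (len(grid), window+1)
    full = inc @ T                                       # peaks 0..window
    use = list(shifts) if shifts else list(range(window + 1))
    return full[:, 0] / full[:, use].sum(axis=1)


def _rms(obs_list, N_map, p, formulas, window, abundances, shifts_map) -> float:
    errs = []
    for obs in obs_list:
        pred = _m0_table(formulas[obs.sterol], np.array([N_map[obs.sterol]]), p,
                         window, abundances, shifts_map.get(obs.sterol))[0]
        errs.append(obs.m0_t - pred)
    return float(np.sqrt(np.mean(np.square(errs))))


def _profile_rms(obs_list, p, grid, formulas, window, abundances, shifts_map,
                 ) -> tuple[float, dict]:
    """RMS at enrichment p with every per-sterol N profiled out.

    Each sterol has one N shared across tissues (the molecule's site count
    is a property of the sterol, not of the tissue); the best integer N on
    the grid minimizes that sterol's summed squared misfit across all its
    tissue observations. Ties break toward the smallest N (argmin order).
    """
    sq_total, n_obs, N_map = 0.0, 0, {}
    for s, group in _by_sterol(obs_list).items():
        table = _m0_table(formulas[s], grid, p, window, abundances,
                          shifts_map.get(s))
        targets = np.array([o.m0_t for o in group])
        errs = ((table[:, None] - targets[None, :]) ** 2).sum(axis=1)
        j = int(np.argmin(errs))
        N_map[s] = int(grid[j])
        sq_total += errs[j]
        n_obs += len(group)
    return float(np.sqrt(sq_total / n_obs)), N_map


def _by_sterol(obs_list) -> dict[str, list]:
    out: dict[str, list] = {}
    for o in obs_list:
        out.setdefault(o.sterol, []).append(o)
    return out


def _profile_scan(obs_list, p_grid, grid, formulas, window, abundances,
                  shifts_map) -> np.ndarray:
    """N-profiled RMS for every p in ``p_grid`` at once (vectorized)."""
    ks = np.arange(window + 1)
    sq_total = np.zeros(len(p_grid))
    n_obs = 0
    for s, group in _by_sterol(obs_list).items():
        T = _nat_lowtri(formulas[s], window, abundances)
        pmf = binom.pmf(ks[None, None, :], grid[None, :, None],
                        p_grid[:, None, None])            # (P, N, K)
        full = pmf @ T
        use = list(shifts_map.get(s) or range(window + 1))
        m0 = full[..., 0] / full[..., use].sum(axis=-1)   # (P, N)
        targets = np.array([o.m0_t for o in group])
        errs = ((m0[:, :, None] - targets[None, None, :]) ** 2).sum(axis=-1)
        sq_total += errs.min(axis=1)
        n_obs += len(group)
    return np.sqrt(sq_total / n_obs)


def joint_estimate_Np(obs: list[AsymptoticObservation],
                      formulas: dict[str, FragmentFormula],
                      init_N: int = 21, window: int = 3,
                      search_range: tuple[int, int] = (18, 30),
                      abundances: IsotopeAbundanceTable = CARBON_ONLY_ABUNDANCES,
                      measurable_shifts: dict[str, tuple[int, ...]] | None = None,
                      p_bounds: tuple[float, float] = (1e-4, 0.5),
                      tol: float = 1e-10, max_iter: int = 100,
                      ) -> JointCalibration:
    """Jointly estimate a global enrichment p and per-(sterol, tissue) N by
    alternating minimization of the RMS misfit of asymptotic M+0 fractions.

    Each sterol carries one N shared across tissues; p is global. The RMS
    surface is nearly degenerate along a joint (N, p) ridge (rescaling p
    while shifting every N preserves the mean label content N*p), so a
    plain alternating scheme started from one p can stall at a local
    minimum. The search therefore first profiles out the integer N values
    (per-sterol best N at each p on a fine p grid) to bracket the global
    minimum, then polishes with alternating iterations: (a) integer-grid N
    per sterol at the current p (ties toward the smallest N), (b) bounded
    1-D minimization of the RMS over p at the current N map. The RMS is
    non-increasing across the alternating iterations; convergence is
    declared when it changes by < ``tol``.

    ``search_range`` defaults to the physiologically plausible band of
    sterol deuterium-site counts (18-30). Widening it re-admits
    lambda-preserving aliases of the solution at implausible N (e.g. every
    N shifted +10 with p rescaled), which measurement noise cannot
    discriminate; narrowing the band is the identifying assumption.

    A single observation cannot pin both parameters ((N, p) trade off along a
    level set of M0_t); such fits are returned with ``degenerate=True``.
    """
    if len(obs) < 1:
        raise InvalidInputError("need at least one asymptotic observation")
    shifts_map = measurable_shifts or {}
    lo, hi = search_range
    grid = np.arange(lo, hi + 1)

    # degenerate labeling: observations at (or above) the natural M+0
    nat = {s: natural_m0(formulas[s], window, abundances, shifts_map.get(s))
           for s in {o.sterol for o in obs}}
    if all(o.m0_t >= nat[o.sterol] - 1e-12 for o in obs):
        warnings.warn("all asymptotic observations at natural abundance; "
                      "p is estimated as 0 (degenerate labeling)")
        N_map = {o.sterol: init_N for o in obs}
        return JointCalibration(0.0, N_map, 0.0, 0, degenerate=True)

    # The RMS surface is ridged: trading p against all the integer N values
    # leaves near-perfect fits at many p, with N-switch kinks every ~0.001
    # in p. Locate the global basin by scanning the N-profiled RMS on a fine
    # p grid, then refine p within the bracketing interval.
    def profile(q: float) -> float:
        return _profile_rms(obs, q, grid, formulas, window, abundances,
                            shifts_map)[0]

    step = 2.5e-4
    p_fine = np.arange(p_bounds[0], p_bounds[1] + step, step)
    vals = _profile_scan(obs, p_fine, grid, formulas, window, abundances,
                         shifts_map)
    # basins can be narrower than the scan step, so refine every competitive
    # local minimum of the scanned profile, not just the global one
    interior = np.flatnonzero((vals[1:-1] <= vals[:-2])
                              & (vals[1:-1] <= vals[2:])) + 1
    candidates = sorted(interior, key=lambda i: vals[i])[:40] or [int(np.argmin(vals))]
    best_p, best_val = float(p_fine[candidates[0]]), float(vals[candidates[0]])
    for i in candidates:
        lo_p = p_fine[max(i - 1, 0)]
        hi_p = p_fine[min(i + 1, len(p_fine) - 1)]
        res = minimize_scalar(profile, bounds=(lo_p, hi_p), method="bounded",
                              options={"xatol": 1e-10})
        if res.fun < best_val:
            best_p, best_val = float(res.x), float(res.fun)
    p = best_p
    _, N_map = _profile_rms(obs, p, grid, formulas, window, abundances,
                            shifts_map)
    last_rms = _rms(obs, N_map, p, formulas, window, abundances, shifts_map)
    for it in range(1, max_iter + 1):
        # (a) integer-grid N per observation at fixed p
        _, N_map = _profile_rms(obs, p, grid, formulas, window, abundances,
                                shifts_map)
        # (b) scalar p at fixed N map
        res = minimize_scalar(
            lambda q: _rms(obs, N_map, q, formulas, window, abundances, shifts_map),
            bounds=p_bounds, method="bounded",
            options={"xatol": 1e-10})
        p = float(res.x)
        rms = float(res.fun)
        if rms > last_rms + 1e-9:
            logger.warning("RMS increased at iteration %d (%.3e -> %.3e)",
                           it, last_rms, rms)
        if abs(last_rms - rms) < tol:
            degenerate = len(obs) == 1
            if degenerate:
                warnings.warn("single observation: (N, p) are jointly "
                              "unidentifiable; returning an RMS-equivalent pair")
            return JointCalibration(p, dict(N_map), rms, it, degenerate)
        last_rms = rms
    raise ConvergenceError(
        f"joint (N, p) estimation did not converge in {max_iter} iterations",
        last_iterate=JointCalibration(p, dict(N_map), last_rms, max_iter))
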