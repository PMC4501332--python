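"""First-order turnover kinetics and internal-standard quantitation.

The labeled fraction of a sterol pool under constant-enrichment labeling
follows g(t) = g_inf * (1 - exp(-k t)): the pool turns over with rate
constant k (per hour) toward an asymptote g_inf (1 when the whole pool is
renewable). The absolute synthesis rate is k times the pool concentration,
which is quantified against a spiked internal standard (d6-sitosterol,
20 ng) relative to the sample's normalizer (protein or tissue mass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, InvalidInputError, QuantitationError
from .isa import TurnoverSeries

__all__ = ["KineticFit", "QuantResult", "fit_first_order",
           "quantify_concentration", "synthesis_rate"]

G_INF_MAX = 1.05    # allows small calibration error above 1
K_MAX = 10.0        # per hour


@dataclass(frozen=True)
class KineticFit:
    """Fitted first-order turnover parameters for one series."""

    g_inf: float
    k: float                  # per hour
    rss: float
    n_obs: int
    se_g_inf: float | None = None
    se_k: float | None = None
    zero_turnover: bool = False
    g_inf_fixed: bool = False

    def __post_init__(self) -> None:
        if self.k < 0 or self.rss < 0:
            raise InvalidInputError("k and rss must be non-negative")
        if not (0.0 <= self.g_inf <= G_INF_MAX):
            raise InvalidInputError(f"g_inf must be in [0, {G_INF_MAX}]")

    def halflife_hr(self) -> float:
        return np.inf if self.k == 0 else float(np.log(2) / self.k)


@dataclass(frozen=True)
class QuantResult:
    """Internal-standard quantitation of one sterol in one sample class."""

    sterol: str
    concentration: float      # ng per unit of normalizer
    normalizer_kind: str      # "protein_ug" or "tissue_mg"
    normalizer_amount: float
    is_amount_ng: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise InvalidInputError("concentration must be >= 0")
        if self.normalizer_amount <= 0:
            raise InvalidInputError("normalizer must be > 0")


def _model(t: np.ndarray, g_inf: float, k: float) -> np.ndarray:
    return g_inf * (1.0 - np.exp(-k * t))


def _init_k(times: np.ndarray, g: np.ndarray, g_inf0: float) -> float:
    """Closed-form k from the earliest time point with usable positive g."""
    for t, gi in sorted(zip(times, g)):
        if t > 0 and 0 < gi < g_inf0:
            return float(-np.log(1.0 - gi / g_inf0) / t)
    return 0.1


def fit_first_order(series: TurnoverSeries, g_inf_fixed: float | None = None,
                    zero_floor: float = 0.02) -> KineticFit:
    """Bounded nonlinear least squares of g(t) = g_inf (1 - exp(-k t)).

    All replicate points enter the loss unweighted. Requires >= 3 distinct
    time points (>= 2 when ``g_inf_fixed`` is supplied). Series whose g never
    rises above ``zero_floor`` are reported as zero turnover (k = 0) rather
    than fitted.
    """
    t, g = series.times, series.g
    needed = 2 if g_inf_fixed is not None else 3
    if series.n_distinct_times() < needed:
        raise InvalidInputError(
            f"need >= {needed} distinct time points, got {series.n_distinct_times()}")

    if np.all(g[t > 0] < zero_floor) if np.any(t > 0) else np.all(np.abs(g) < zero_floor):
        rss = float(np.sum(np.square(g)))
        return KineticFit(g_inf=0.0, k=0.0, rss=rss, n_obs=len(g),
                          zero_turnover=True, g_inf_fixed=g_inf_fixed is not None)

    if g_inf_fixed is not None:
        def resid(theta):
            return _model(t, g_inf_fixed, theta[0]) - g
        x0 = [_init_k(t, g, g_inf_fixed)]
        lb, ub = [0.0], [K_MAX]
    else:
        g_inf0 = float(np.clip(np.max(g), 1e-3, G_INF_MAX))

        def resid(theta):
            return _model(t, theta[0], theta[1]) - g
        x0 = [g_inf0, min(_init_k(t, g, g_inf0), K_MAX)]
        lb, ub = [0.0, 0.0], [G_INF_MAX, K_MAX]

    sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    if not sol.success:
        raise FitError(f"kinetic fit failed for {series.sterol}: {sol.message}")

    rss = float(np.sum(sol.fun ** 2))
    dof = len(g) - len(sol.x)
    se = (None, None)
    if dof > 0 and rss > 0:
        try:
            jtj_inv = np.linalg.inv(sol.jac.T @ sol.jac)
            se_vec = np.sqrt(np.diag(jtj_inv) * rss / dof)
            se = tuple(se_vec)
        except np.linalg.LinAlgError:
            pass

    if g_inf_fixed is not None:
        return KineticFit(g_inf=float(g_inf_fixed), k=float(sol.x[0]), rss=rss,
                          n_obs=len(g), se_k=se[0] if se[0] is not None else None,
                          g_inf_fixed=True)
    return KineticFit(g_inf=float(sol.x[0]), k=float(sol.x[1]), rss=rss,
                      n_obs=len(g), se_g_inf=se[0], se_k=se[1])


def quantify_concentration(analyte_area: float, is_area: float,
                           is_amount_ng: float, normalizer: float,
                           response_factor: float = 1.0,
                           sterol: str = "", normalizer_kind: str = "protein_ug",
                           ) -> QuantResult:
    """Concentration relative to the internal standard:
    (analyte / IS area) * IS amount * response factor / normalizer."""
    if is_area <= 0:
        raise QuantitationError("internal standard area must be > 0")
    if normalizer <= 0:
        raise QuantitationError("normalizer amount must be > 0")
    if analyte_area < 0:
        raise InvalidInputError("analyte area must be >= 0")
    conc = analyte_area / is_area * is_amount_ng * response_factor / normalizer
    return QuantResult(sterol=sterol, concentration=float(conc),
                       normalizer_kind=normalizer_kind,
                       normalizer_amount=float(normalizer),
                       is_amount_ng=float(is_amount_ng))


def synthesis_rate(fit: KineticFit, quant: QuantResult) -> float:
    """Absolute synthesis rate = k * concentration (ng / normalizer / hr)."""
    return fit.k * quant.concentration
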