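"""Growth, uptake and secretion rates from culture time series.

Rates follow the standard exponential-phase conventions: the growth rate is
the slope of ln(OD) versus time; exchange rates exploit the fact that under
balanced exponential growth extracellular concentration is linear in
biomass concentration, so ``q = mu * dC/dX`` (mmol g_CDW^-1 h^-1, negative
for consumption, positive for secretion).  Carbon partitioning splits the
total carbon uptake rate into biomass, secretion and other (CO2 and
unmeasured) effluxes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class PhysiologyError(ValueError):
    pass


@dataclass
class GrowthSeries:
    """OD600 time course with optional extracellular concentrations (mM)."""

    time_h: np.ndarray
    od600: np.ndarray
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)
    conversion_gcdw_per_od: float | None = None  # g_CDW L^-1 OD600^-1

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if np.any(np.diff(self.time_h) <= 0):
            raise PhysiologyError("time must be strictly increasing")
        if np.any(self.od600 <= 0):
            raise PhysiologyError("OD600 must be positive")
        self.concentrations = {k: np.asarray(v, dtype=float)
                               for k, v in self.concentrations.items()}

    def window_mask(self, window: tuple[float, float] | None):
        if window is None:
            return np.ones_like(self.time_h, dtype=bool)
        lo, hi = window
        return (self.time_h >= lo) & (self.time_h <= hi)

    def biomass_gl(self) -> np.ndarray:
        if self.conversion_gcdw_per_od is None:
            raise PhysiologyError("OD -> g_CDW conversion factor missing")
        return self.od600 * self.conversion_gcdw_per_od


@dataclass
class PhysioRates:
    mu: float                       # h^-1
    mu_sd: float
    uptake: dict[str, float] = field(default_factory=dict)   # positive magnitudes
    secretion: dict[str, float] = field(default_factory=dict)
    partition: dict[str, float] = field(default_factory=dict)


def growth_rate(series: GrowthSeries,
                window: tuple[float, float] | None = None) -> tuple[float, float]:
    """Exponential growth rate: least-squares slope of ln(OD) vs time."""
    mask = series.window_mask(window)
    if mask.sum() < 3:
        raise PhysiologyError("need at least 3 points in the window")
    res = stats.linregress(series.time_h[mask], np.log(series.od600[mask]))
    return float(res.slope), float(res.stderr)


def exchange_rate(series: GrowthSeries, compound: str, mu: float,
                  window: tuple[float, float] | None = None,
                  ) -> tuple[float, float]:
    """Specific exchange rate of a compound (negative = consumption).

    Regresses concentration (mM) on biomass concentration (g_CDW/L); under
    exponential growth the slope is dC/dX = q/mu, so q = mu * slope.
    """
    X = series.biomass_gl()
    mask = series.window_mask(window)
    if compound not in series.concentrations:
        raise PhysiologyError(f"no concentration series for {compound!r}")
    C = series.concentrations[compound]
    if mask.sum() < 3:
        raise PhysiologyError("need at least 3 points in the window")
    res = stats.linregress(X[mask], C[mask])
    return float(mu * res.slope), float(abs(mu) * res.stderr)


def classify_secretion(series: GrowthSeries, compound: str,
                       window: tuple[float, float] | None = None,
                       alpha: float = 0.05) -> bool:
    """A compound is a secretion if its concentration rises significantly
    (one-sided p < alpha) across the exponential window."""
    mask = series.window_mask(window)
    C = series.concentrations[compound]
    res = stats.linregress(series.time_h[mask], C[mask])
    if res.slope <= 0:
        return False
    p_one_sided = res.pvalue / 2.0
    return p_one_sided < alpha


def carbon_partition(mu: float, uptake: dict[str, float],
                     secretion: dict[str, float],
                     carbons: dict[str, int],
                     biomass_c_content: float = 40.0,
                     ) -> dict[str, float]:
    """Partition the total carbon uptake rate into biomass / secretion / other.

    ``uptake`` and ``secretion`` are positive rate magnitudes
    (mmol g_CDW^-1 h^-1); ``biomass_c_content`` is mmol carbon per g_CDW
    (typical heterotroph value by default — configurable).
    """
    total_c = sum(q * carbons[c] for c, q in uptake.items())
    if total_c <= 0:
        raise PhysiologyError("total carbon uptake must be positive")
    biomass = mu * biomass_c_content / total_c
    secreted = sum(q * carbons[c] for c, q in secretion.items()) / total_c
    other = 1.0 - biomass - secreted
    if other < -1e-9:
        warnings.warn("carbon balance exceeds uptake; clipping 'other' to 0",
                      stacklevel=2)
    other = max(other, 0.0)
    s = biomass + secreted + other
    return {"biomass": biomass / s, "secretion": secreted / s,
            "other": other / s}


def physiology_summary(series: GrowthSeries,
                       substrates: list[str],
                       carbons: dict[str, int],
                       window: tuple[float, float] | None = None,
                       biomass_c_content: float = 40.0) -> PhysioRates:
    """Growth rate, exchange rates and carbon partition in one pass."""
    mu, mu_sd = growth_rate(series, window)
    uptake, secretion = {}, {}
    for compound in series.concentrations:
        q, _ = exchange_rate(series, compound, mu, window)
        if compound in substrates:
            if q >= 0:
                raise PhysiologyError(f"substrate {compound!r} not consumed")
            uptake[compound] = -q
        elif classify_secretion(series, compound, window):
            secretion[compound] = q
    rates = PhysioRates(mu, mu_sd, uptake, secretion)
    if uptake:
        rates.partition = carbon_partition(mu, uptake, secretion, carbons,
                                           biomass_c_content)
    return rates
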