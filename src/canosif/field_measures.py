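"""Chamber CO2 fluxes, leaf chlorophyll and grain yield.

Closed-chamber fluxes use the static-chamber ideal-gas conversion: the
CO2 mixing-ratio trend (ppm s-1, ordinary least squares over the record)
is scaled by P*V / (R*T*A) to a flux in umol m-2 s-1, the sign of the
trend preserved (negative = net uptake).  GPP is |NEE| + |ER|, the sum of
the magnitudes of the light (net ecosystem exchange) and dark (ecosystem
respiration) chamber fluxes.

Chlorophyll follows the spectrophotometric two-wavelength equations on
absorbances at 645 and 663 nm; grain yield scales the fresh harvest mass
by the hundred-grain dry-to-fresh ratio and the plot area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError

#: Universal gas constant, J mol-1 K-1.
R_GAS = 8.314462618
#: Defaults when chamber air temperature / pressure were not logged.
DEFAULT_AIR_TEMP_K = 298.15
DEFAULT_PRESSURE_PA = 101325.0


@dataclass
class ChamberSeries:
    """One closed-chamber CO2 record.

    times are seconds since chamber closure (strictly increasing; the
    instrument logs every 2 s for ~60 s), co2 in ppm (umol mol-1).
    base_area 0.25 m2 for the 50 x 50 cm chamber; height 0.5 m early
    season, 1.0 m once the canopy outgrew the short chamber.
    """

    times: np.ndarray
    co2: np.ndarray
    base_area: float = 0.25
    height: float = 0.5
    air_temp: float = DEFAULT_AIR_TEMP_K  # K
    pressure: float = DEFAULT_PRESSURE_PA  # Pa
    mode: str = "NEE"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.co2 = np.asarray(self.co2, dtype=float)
        if self.times.size != self.co2.size:
            raise DegenerateInputError("times and co2 must have equal length")
        if self.times.size < 2:
            raise InsufficientDataError("chamber series needs >= 2 samples")
        if not np.all(np.diff(self.times) > 0):
            raise DegenerateInputError("times must be strictly increasing")
        if self.base_area <= 0:
            raise DegenerateInputError("chamber base area must be positive")
        if self.height <= 0:
            raise DegenerateInputError("chamber height must be positive")
        if self.mode not in ("NEE", "ER"):
            raise DegenerateInputError(f"mode {self.mode!r} must be 'NEE' or 'ER'")

    @property
    def volume(self) -> float:
        """Chamber volume, m3."""
        return self.base_area * self.height


@dataclass(frozen=True)
class ChamberFlux:
    """Flux with its fit diagnostics."""

    flux: float  # umol m-2 s-1
    slope: float  # ppm s-1
    r_squared: float
    n: int
    mode: str


@dataclass(frozen=True)
class GrainSample:
    """Hundred-grain weights and plot harvest for one plot."""

    hundred_dry_g: float
    hundred_fresh_g: float
    total_fresh_g: float
    plot_area_m2: float

    def __post_init__(self) -> None:
        if self.hundred_fresh_g <= 0:
            raise DegenerateInputError("hundred-grain fresh weight must be > 0")
        if not 0 < self.hundred_dry_g <= self.hundred_fresh_g:
            raise DegenerateInputError(
                "hundred-grain dry weight must be in (0, fresh weight]"
            )
        if self.total_fresh_g < 0:
            raise DegenerateInputError("total fresh weight must be >= 0")
        if self.plot_area_m2 <= 0:
            raise DegenerateInputError("plot area must be positive")


@dataclass(frozen=True)
class LeafAbsorbance:
    """Spectrophotometer readings of one leaf extract (~0.1 g tissue)."""

    a645: float
    a663: float
    sample_mass_g: float = 0.1

    def __post_init__(self) -> None:
        if self.a645 < 0 or self.a663 < 0:
            raise DegenerateInputError("absorbances must be >= 0")


@dataclass(frozen=True)
class ChlorophyllResult:
    """Chlorophyll a, b and a+b from the two-wavelength equations."""

    c_a: float
    c_b: float
    c_ab: float  # scaled by 0.0094e6 per the standard formula; ug/cm2 scale


def flux_from_chamber(series: ChamberSeries, discard_seconds: float = 0.0) -> ChamberFlux:
    """CO2 flux from one chamber record, umol m-2 s-1.

    The ppm s-1 trend comes from an OLS fit of co2 on time (optionally
    discarding an initial mixing transient), then

        flux = slope * P * V / (R * T * A)

    with V = base_area * height, so flux is exactly linear in the fitted
    slope and in the V/A ratio.  The fit R^2 is returned as a mixing
    diagnostic; the slope's sign is preserved (negative = uptake).
    """
    keep = series.times >= series.times[0] + discard_seconds
    t = series.times[keep]
    c = series.co2[keep]
    if t.size < 2:
        raise InsufficientDataError("fewer than 2 samples after transient discard")
    if np.ptp(t) == 0:
        raise DegenerateInputError("zero time span in chamber record")
    fit = stats.linregress(t, c)
    slope = float(fit.slope)
    r2 = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue) ** 2
    scale = (
        series.pressure * series.volume / (R_GAS * series.air_temp * series.base_area)
    )
    return ChamberFlux(
        flux=slope * scale, slope=slope, r_squared=r2, n=int(t.size), mode=series.mode
    )


def gpp_from_nee_er(nee: float, er: float) -> float:
    """GPP = |NEE| + |ER|, umol m-2 s-1 (sign and order insensitive)."""
    return abs(nee) + abs(er)


def chlorophyll_ab(leaf: LeafAbsorbance) -> ChlorophyllResult:
    """Chlorophyll a, b and a+b from absorbances at 663 and 645 nm.

    C_a = 0.00127*A663 - 0.000269*A645
    C_b = 0.00229*A645 - 0.000468*A663
    C_ab = (C_a + C_b) * 0.0094 * 1e6
    """
    c_a = 0.00127 * leaf.a663 - 0.000269 * leaf.a645
    c_b = 0.00229 * leaf.a645 - 0.000468 * leaf.a663
    c_ab = (c_a + c_b) * 0.0094 * 1.0e6
    return ChlorophyllResult(c_a=c_a, c_b=c_b, c_ab=c_ab)


def grain_yield(sample: GrainSample) -> float:
    """Grain yield in kg m-2.

    The hundred-grain dry-to-fresh ratio scales the total fresh harvest
    to dry mass; division by the harvested plot area and g->kg conversion
    gives the areal figure.
    """
    dry_mass_g = (
        sample.hundred_dry_g / sample.hundred_fresh_g * sample.total_fresh_g
    )
    return dry_mass_g / sample.plot_area_m2 / 1000.0
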