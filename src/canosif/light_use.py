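"""fPAR from NDVI, APAR from shortwave, and Beer-Lambert LAI inversion.

fPAR is the affine proxy 1.37 * NDVI - 0.17; APAR converts shortwave
radiation (W m-2) to absorbed photon flux (umol m-2 s-1) through the PAR
fraction 0.5 and the quantum conversion 4.55 umol J-1; LAI follows from
fPAR = 1 - exp(-k LAI) with extinction coefficient k = 0.5.

The affine fPAR proxy can leave [0, 1]; for pipeline use values are
clamped to [0, fpar_cap] (cap 0.95 keeps the inverted LAI finite) while
the raw value stays available for diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, SaturationError


@dataclass(frozen=True)
class LightUseParams:
    """Constants of the light-use chain.

    eta_q : PAR fraction of shortwave radiation (0.5).
    mu : irradiance to photon-flux conversion, umol J-1 (4.55).
    k : canopy extinction coefficient (0.5).
    fpar_slope, fpar_intercept : coefficients of the NDVI->fPAR proxy.
    fpar_cap : upper clamp applied before LAI inversion.
    """

    eta_q: float = 0.5
    mu: float = 4.55
    k: float = 0.5
    fpar_slope: float = 1.37
    fpar_intercept: float = -0.17
    fpar_cap: float = 0.95

    def __post_init__(self) -> None:
        if min(self.eta_q, self.mu, self.k, self.fpar_slope) <= 0:
            raise DegenerateInputError("eta_q, mu, k and fpar_slope must be positive")
        if not 0.0 < self.fpar_cap < 1.0:
            raise DegenerateInputError("fpar_cap must lie in (0, 1)")


DEFAULT_PARAMS = LightUseParams()


def fpar_from_ndvi(
    ndvi: float, params: LightUseParams = DEFAULT_PARAMS, clamp: bool = True
) -> float:
    """fPAR = 1.37 * NDVI - 0.17, clamped to [0, fpar_cap] unless clamp=False."""
    if not -1.0 <= ndvi <= 1.0:
        raise DegenerateInputError(f"NDVI {ndvi} outside [-1, 1]")
    raw = params.fpar_slope * ndvi + params.fpar_intercept
    if not clamp:
        return raw
    return min(max(raw, 0.0), params.fpar_cap)


def ndvi_from_fpar(fpar: float, params: LightUseParams = DEFAULT_PARAMS) -> float:
    """Invert the affine fPAR proxy (used by the season generator)."""
    return (fpar - params.fpar_intercept) / params.fpar_slope


def apar(rs: float, fpar: float, params: LightUseParams = DEFAULT_PARAMS) -> float:
    """APAR = R_s * eta_q * mu * fPAR, umol m-2 s-1."""
    if rs < 0:
        raise DegenerateInputError("shortwave radiation must be >= 0")
    if not 0.0 <= fpar <= 1.0:
        raise DegenerateInputError(f"fPAR {fpar} outside [0, 1]")
    return rs * params.eta_q * params.mu * fpar


def fpar_from_lai(lai: float, params: LightUseParams = DEFAULT_PARAMS) -> float:
    """Beer-Lambert forward form fPAR = 1 - exp(-k LAI)."""
    if lai < 0:
        raise DegenerateInputError("LAI must be >= 0")
    return 1.0 - math.exp(-params.k * lai)


def lai_from_fpar(
    fpar: float, params: LightUseParams = DEFAULT_PARAMS, cap: bool = True
) -> float:
    """Invert Beer-Lambert: LAI = -ln(1 - fPAR) / k.

    With ``cap`` set (default) fPAR is first clamped to [0, fpar_cap];
    otherwise fPAR >= 1 raises ``SaturationError``.
    """
    if cap:
        fpar = min(max(fpar, 0.0), params.fpar_cap)
    if fpar >= 1.0:
        raise SaturationError(f"fPAR {fpar} >= 1: LAI diverges")
    if fpar < 0.0:
        raise DegenerateInputError(f"fPAR {fpar} < 0")
    return -math.log(1.0 - fpar) / params.k


def add_light_use_columns(
    daily: pd.DataFrame, params: LightUseParams = DEFAULT_PARAMS
) -> pd.DataFrame:
    """Add fpar_raw, fpar, apar and lai to a daily table with ndvi, rs_wm2."""
    out = daily.copy()
    ndvi = out["ndvi"].to_numpy(float)
    raw = params.fpar_slope * ndvi + params.fpar_intercept
    fpar = np.clip(raw, 0.0, params.fpar_cap)
    out["fpar_raw"] = raw
    out["fpar"] = fpar
    out["apar"] = out["rs_wm2"].to_numpy(float) * params.eta_q * params.mu * fpar
    out["lai"] = -np.log1p(-fpar) / params.k
    return out
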