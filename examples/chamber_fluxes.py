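"""Closed-chamber CO2 records to NEE, ER and GPP.

Simulates a one-minute light-chamber (NEE) and dark-chamber (ER) record
at the instrument cadence (2 s), fits the concentration trend and
converts it to a flux with the ideal-gas chamber equation.
"""

import numpy as np

from canosif import ChamberSeries, flux_from_chamber, gpp_from_nee_er

rng = np.random.default_rng(0)
t = np.arange(0.0, 62.0, 2.0)

# light chamber: canopy uptake dominates -> CO2 falls
nee_series = ChamberSeries(
    times=t, co2=420.0 - 0.55 * t + rng.normal(0, 0.3, t.size),
    base_area=0.25, height=0.5, air_temp=300.15, pressure=101325.0, mode="NEE",
)
# dark chamber: respiration only -> CO2 rises
er_series = ChamberSeries(
    times=t, co2=420.0 + 0.18 * t + rng.normal(0, 0.3, t.size),
    base_area=0.25, height=0.5, air_temp=300.15, pressure=101325.0, mode="ER",
)

nee = flux_from_chamber(nee_series)
er = flux_from_chamber(er_series)
gpp = gpp_from_nee_er(nee.flux, er.flux)

print(f"NEE: {nee.flux:7.2f} umol m-2 s-1  (slope {nee.slope:.3f} ppm/s, R2 {nee.r_squared:.4f})")
print(f"ER : {er.flux:7.2f} umol m-2 s-1  (slope {er.slope:.3f} ppm/s, R2 {er.r_squared:.4f})")
print(f"GPP: {gpp:7.2f} umol m-2 s-1  (= |NEE| + |ER|)")
# Negative NEE means net uptake; GPP adds back the respiration the
# light-chamber measurement hides.
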