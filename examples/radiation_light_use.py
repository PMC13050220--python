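"""From site location and sunshine hours to absorbed PAR and LAI.

Computes extraterrestrial radiation and day length for the rice site
(29.45 deg N) in mid-July, converts sunshine duration to incident
shortwave with the Angstrom-Prescott relation, then chains NDVI ->
fPAR -> APAR and inverts Beer-Lambert for LAI.
"""

from canosif import radiation as rad
from canosif import apar, fpar_from_ndvi, lai_from_fpar

latitude_deg, doy, sunshine_hours = 29.45, 198, 8.0

geom = rad.solar_geometry(latitude_deg, doy)
rec = rad.radiation_record(latitude_deg, doy, sunshine_hours)
print(f"DOY {doy} at {latitude_deg} N:")
print(f"  declination      {geom.declination:.4f} rad")
print(f"  day length       {geom.day_length:.2f} h")
print(f"  R_a              {rec.ra:.2f} MJ m-2 d-1")
print(f"  sunshine n/N     {rec.sunshine_fraction:.3f}")
print(f"  R_s              {rec.rs:.1f} W m-2")

ndvi = 0.8
fpar = fpar_from_ndvi(ndvi)
apar_val = apar(rec.rs, fpar)
lai = lai_from_fpar(fpar)
print(f"NDVI {ndvi} -> fPAR {fpar:.3f} -> APAR {apar_val:.1f} umol m-2 s-1"
      f" -> LAI {lai:.2f}")
# APAR is the photon flux the canopy absorbs; LAI is the leaf area per
# ground area implied by that interception under Beer-Lambert (k = 0.5).
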