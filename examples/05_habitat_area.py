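"""Monthly two-part habitat availability from SIC and SST isoclines.

Open-water habitat is the area between the 5% sea-ice-concentration
isocline and the 2 degC isotherm (180 W to 0 W, land-clipped); the
marginal ice zone (MIZ) is the 5-50% SIC band.  Isoclines are traced by
marching squares, turned into polygons, differenced against the land
mask, and measured in an equal-area projection.
"""

from pengwinter.habitat import habitat_area, habitat_area_raster
from pengwinter.synthetic import SimulationConfig, generate_env_grids

env = generate_env_grids(SimulationConfig(seed=1))
print("month  open_water_Mkm2  MIZ_Mkm2  (raster check, %)")
for m in env.monthly["month"].values:
    sst = env.monthly["sst"].sel(month=m)
    sic = env.monthly["sic"].sel(month=m)
    idx = habitat_area(sst, sic, env.land_mask, int(m))
    oracle = habitat_area_raster(sst, sic, env.land_mask, int(m))
    dev = 100 * abs(idx.open_water_km2 / oracle.open_water_km2 - 1)
    print(f"{int(m):5d}  {idx.open_water_km2 / 1e6:15.2f}  "
          f"{idx.miz_km2 / 1e6:8.2f}  ({dev:.2f})")
# Open water shrinks toward late winter as the ice edge advances north
# faster than the 2 degC isotherm retreats; the MIZ stays a compara-
# tively narrow, slowly widening band.
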