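"""PM2.5 <-> US AQI conversion and health-band categorization."""

from gazecog import pm25_to_aqi, aqi_to_pm25, aqi_category

for conc in (5.0, 12.0, 35.4, 55.5, 150.5, 250.5):
    aqi = pm25_to_aqi(conc)
    print(f"PM2.5 {conc:6.1f} ug/m3 -> AQI {aqi:5.1f} ({aqi_category(aqi)})")

print()
for aqi in (50, 100, 150, 186, 207, 301):
    print(f"AQI {aqi:3d} ({aqi_category(aqi):20s}) "
          f"-> PM2.5 {aqi_to_pm25(aqi):6.1f} ug/m3")
# The mapping is the EPA piecewise-linear breakpoint table; the two
# functions are exact mutual inverses at every breakpoint.
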