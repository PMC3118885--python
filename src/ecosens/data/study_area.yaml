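# Study-area metadata for the Yicheng City case study (Hubei, China),
# with the text/table conflicts in the source recorded per fixture.
name: Yicheng City
province: Hubei
longitude: "111°57'–112°45' E"
latitude: "31°27'–31°54' N"
east_west_km: 76
north_south_km: 53
total_area_km2: 2045
total_area_hm2: 204500
annual_mean_temperature_c: 16
annual_rainfall_mm: [850, 1000]
annual_sunlight_h: 1932
relative_humidity_pct: 76
conflicts:
  - "narrative cites 13.91% for the slightly sensitive soil class where the table prints 29.84%"
  - "biodiversity moderate share printed 70.16% in the table, 70.18% in the narrative"
  - "synthesis narrative cites the moderate area as 38,218.58 hm² where the table prints 53,317.27 hm²"
  - "table areas for the synthesis sum to 205,145.34 hm², not the 204,500 hm² implied by 2,045 km²"
  - "synthesis table prints the extreme share as 14.4 (i.e. 14.40 at 2 d.p.)"
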