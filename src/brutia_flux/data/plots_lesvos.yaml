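# Nine permanent Pinus brutia monitoring plots on the island of Lesvos,
# Greece: four across a post-fire chronosequence (group: postfire) and five
# along an elevation gradient on Mt Olympos (group: elevation).
#
# latitude/longitude (decimal degrees), stand_age (years), elevation (m asl),
# lai (m2 m-2) and the plot climate summaries (annual mean air temperature
# t_a, annual mean daily minimum t_min / maximum t_max, annual mean relative
# humidity rh_a, and annual mean soil temperature ts_a where soil sensors
# were installed; temperatures degC, humidity %) are the published
# monitoring-network values.
#
# The soil block (texture class, depth_mm, and any bulk-density override)
# is NOT published per plot. The entries below are SYNTHETIC assignments:
# depths are drawn from the reported 20-40 cm range for these shallow
# ophiolitic soils, and the 72-year-old plot is given the "Very Fine"
# texture its high soil-moisture behaviour is attributed to. Treat them as
# editable defaults, not measurements.
plots:
  - id: AMAL
    group: postfire
    latitude: 39.02
    longitude: 26.59
    stand_age: 13
    elevation: 316
    lai: 0.67
    t_a: 17.4
    t_min: 12.6
    t_max: 23.1
    rh_a: 68.7
    soil: {texture: Medium, depth_mm: 300}
  - id: PEV
    group: postfire
    latitude: 39.16
    longitude: 26.37
    stand_age: 40
    elevation: 213
    lai: 1.66
    t_a: 17.3
    t_min: 10.6
    t_max: 25.4
    rh_a: 67.2
    soil: {texture: Medium, depth_mm: 350}
  - id: LML
    group: postfire
    latitude: 39.16
    longitude: 26.38
    stand_age: 72
    elevation: 166
    lai: 2.13
    t_a: 16.6
    t_min: 9.2
    t_max: 24.7
    rh_a: 70.8
    soil: {texture: Very Fine, depth_mm: 400}
  - id: ACHL
    group: postfire
    latitude: 39.13
    longitude: 26.30
    stand_age: 92
    elevation: 261
    lai: 1.67
    t_a: 17.3
    t_min: 10.8
    t_max: 26.9
    rh_a: 66.6
    soil: {texture: Medium Fine, depth_mm: 350}
  - id: OLY1
    group: elevation
    latitude: 39.09
    longitude: 26.33
    stand_age: 82
    elevation: 350
    lai: 4.26
    t_a: 16.5
    t_min: 10.3
    t_max: 25.8
    rh_a: 62.5
    ts_a: 15.8
    soil: {texture: Medium Fine, depth_mm: 400}
  - id: OLY2
    group: elevation
    latitude: 39.09
    longitude: 26.33
    stand_age: 95
    elevation: 450
    lai: 2.08
    t_a: 15.7
    t_min: 10.5
    t_max: 21.8
    rh_a: 68.5
    ts_a: 15.4
    soil: {texture: Medium, depth_mm: 350}
  - id: OLY3
    group: elevation
    latitude: 39.09
    longitude: 26.33
    stand_age: 96
    elevation: 550
    lai: 1.23
    t_a: 15.4
    t_min: 10.4
    t_max: 21.6
    rh_a: 69.6
    ts_a: 14.9
    soil: {texture: Medium, depth_mm: 300}
  - id: OLY4
    group: elevation
    latitude: 39.08
    longitude: 26.33
    stand_age: 64
    elevation: 650
    lai: 1.23
    t_a: 14.2
    t_min: 8.8
    t_max: 20.5
    rh_a: 71.8
    ts_a: 14.3
    soil: {texture: Medium, depth_mm: 250}
  - id: OLY5
    group: elevation
    latitude: 39.08
    longitude: 26.34
    stand_age: 90
    elevation: 750
    lai: 0.98
    t_a: 12.6
    t_min: 8.5
    t_max: 18.3
    rh_a: 76.0
    ts_a: 12.3
    soil: {texture: Coarse, depth_mm: 200}
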