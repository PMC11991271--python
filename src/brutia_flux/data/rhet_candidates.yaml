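# Candidate fixed-effect structures for the empirical soil heterotrophic
# respiration model, fitted on the natural-log flux scale with a random
# intercept per plot. Terms: ts = soil temperature (degC), ts2 = ts^2,
# theta = volumetric soil water content (m3 m-3), theta2 = theta^2,
# loglai = ln(leaf area index), ts_theta = ts * theta. Every model includes
# an intercept. The registry spans the usual temperature-only, Gaussian
# temperature (quadratic on the log scale), moisture-limited and
# substrate-proxy (LAI) families; M09 is the full
# temperature-quadratic + moisture-quadratic + log-LAI form.
candidates:
  - {id: M01_t, terms: [ts]}
  - {id: M02_tt2, terms: [ts, ts2]}
  - {id: M03_w, terms: [theta]}
  - {id: M04_ww2, terms: [theta, theta2]}
  - {id: M05_tw, terms: [ts, theta]}
  - {id: M06_tt2w, terms: [ts, ts2, theta]}
  - {id: M07_tww2, terms: [ts, theta, theta2]}
  - {id: M08_tt2ww2, terms: [ts, ts2, theta, theta2]}
  - {id: M09_tt2ww2l, terms: [ts, ts2, theta, theta2, loglai]}
  - {id: M10_twl, terms: [ts, theta, loglai]}
  - {id: M11_full_int, terms: [ts, ts2, theta, theta2, loglai, ts_theta]}
  - {id: M12_twint, terms: [ts, theta, ts_theta]}
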