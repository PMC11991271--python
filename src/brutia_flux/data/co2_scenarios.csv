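# Atmospheric CO2 concentrations (ppm) by decade and emissions scenario.
# Transcribed (decadal values, annual-mean mixing ratios) from the published
# RCP concentration database of Meinshausen et al. (2011), Climatic Change
# 109:213-241 (http://www.pik-potsdam.de/~mmalte/rcps/). Historical values
# (1970-2000) are common to both pathways. The "baseline" column holds the
# late-1990s concentration fixed, for present-climate control runs.
# Intermediate years are obtained by linear interpolation.
year,baseline,rcp45,rcp85
1970,368.0,325.7,325.7
1980,368.0,338.7,338.7
1990,368.0,353.1,353.1
2000,368.0,368.9,368.9
2010,368.0,389.1,389.3
2020,368.0,411.1,415.8
2030,368.0,435.0,448.8
2040,368.0,460.8,489.4
2050,368.0,486.5,540.5
2060,368.0,508.9,603.5
2070,368.0,524.3,677.1
2080,368.0,531.1,758.2
2090,368.0,533.7,844.8
2100,368.0,538.4,935.9
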