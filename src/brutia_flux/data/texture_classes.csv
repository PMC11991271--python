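# Campbell water-retention and bucket parameters per European soil texture
# class (Coarse / Medium / Medium Fine / Fine / Very Fine, the five classes
# of the European Soil Database texture triangle). Values are representative
# class means assembled from published pedotransfer compilations for
# European soils (Wosten et al. 1999, Geoderma 90:169-185; Campbell 1974,
# Soil Sci. 117:311-314; Clapp & Hornberger 1978, WRR 14:601-604), rounded
# to class-level precision. theta_* in m3 m-3; psi_e is the air-entry
# potential magnitude in MPa; b is the dimensionless Campbell retention
# exponent; rho_soil is a default bulk density in g cm-3 (site values may
# override it).
class,theta_s,theta_r,theta_fc,psi_e,b,rho_soil
Coarse,0.40,0.025,0.12,0.0015,3.0,1.45
Medium,0.44,0.050,0.26,0.0030,4.5,1.35
Medium Fine,0.46,0.080,0.32,0.0040,5.5,1.30
Fine,0.48,0.100,0.36,0.0050,7.0,1.25
Very Fine,0.51,0.120,0.40,0.0060,9.0,1.20
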