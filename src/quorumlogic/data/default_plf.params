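# Canonical default promoter-logic parameter set (arbitrary fluorescence
# units; density in OD600). hill_m/hill_n follow the standard fixed-m
# fitting protocol (m = 2) and the LuxR-DNA cooperativity n = 1.45.
basal_fraction = 0.008
ahl_luxr_halfsat = 100.0
luxr_dna_halfsat = 40.0
hill_m = 2.0
hill_n = 1.45
ahl_density_const = 20.0
density = 0.1
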