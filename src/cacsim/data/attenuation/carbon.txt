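# Mass attenuation coefficients mu/rho (cm^2/g) vs photon energy (keV)
# for carbon. Values follow the public NIST XCOM tabulation style on a
# coarse grid; interpolate log-log. Nominal density: 2.267 g/cm^3.
# energy_keV  mu_over_rho_cm2_per_g
10         2.373
15         0.8071
20         0.442
30         0.2562
40         0.2076
50         0.1871
60         0.1753
80         0.161
100        0.1514
150        0.1347
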