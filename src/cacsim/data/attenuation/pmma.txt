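# Mass attenuation coefficients mu/rho (cm^2/g) vs photon energy (keV)
# for pmma. Values follow the public NIST XCOM tabulation style on a
# coarse grid; interpolate log-log. Nominal density: 1.19 g/cm^3.
# energy_keV  mu_over_rho_cm2_per_g
10         3.357
15         1.101
20         0.5714
30         0.3032
40         0.235
50         0.2074
60         0.1924
80         0.1751
100        0.1641
150        0.1456
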