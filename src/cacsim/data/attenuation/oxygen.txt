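# Mass attenuation coefficients mu/rho (cm^2/g) vs photon energy (keV)
# for oxygen. Values follow the public NIST XCOM tabulation style on a
# coarse grid; interpolate log-log. Nominal density: 0.0013315 g/cm^3.
# energy_keV  mu_over_rho_cm2_per_g
10         5.952
15         1.836
20         0.8651
30         0.3779
40         0.2585
50         0.2132
60         0.1907
80         0.1678
100        0.1551
150        0.1361
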