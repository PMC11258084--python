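# Mass attenuation coefficients mu/rho (cm^2/g) vs photon energy (keV)
# for water. Values follow the public NIST XCOM tabulation style on a
# coarse grid; interpolate log-log. Nominal density: 1.0 g/cm^3.
# energy_keV  mu_over_rho_cm2_per_g
10         5.329
15         1.673
20         0.8096
30         0.3756
40         0.2683
50         0.2269
60         0.2059
80         0.1837
100        0.1707
150        0.1505
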