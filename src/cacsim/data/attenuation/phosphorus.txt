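# Mass attenuation coefficients mu/rho (cm^2/g) vs photon energy (keV)
# for phosphorus. Values follow the public NIST XCOM tabulation style on a
# coarse grid; interpolate log-log. Nominal density: 2.2 g/cm^3.
# energy_keV  mu_over_rho_cm2_per_g
10         40.27
15         12.34
20         5.242
30         1.7
40         0.8096
50         0.5043
60         0.374
80         0.2589
100        0.214
150        0.1657
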