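# Mass attenuation coefficients mu/rho (cm^2/g) vs photon energy (keV)
# for nitrogen. Values follow the public NIST XCOM tabulation style on a
# coarse grid; interpolate log-log. Nominal density: 0.0011653 g/cm^3.
# energy_keV  mu_over_rho_cm2_per_g
10         3.879
15         1.236
20         0.6178
30         0.3066
40         0.2288
50         0.198
60         0.1817
80         0.1639
100        0.1529
150        0.1353
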