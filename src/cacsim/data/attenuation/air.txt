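# Mass attenuation coefficients mu/rho (cm^2/g) vs photon energy (keV)
# for air. Values follow the public NIST XCOM tabulation style on a
# coarse grid; interpolate log-log. Nominal density: 0.0012048 g/cm^3.
# energy_keV  mu_over_rho_cm2_per_g
10         5.12
15         1.614
20         0.7779
30         0.3538
40         0.2485
50         0.208
60         0.1875
80         0.1662
100        0.1541
150        0.1356
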