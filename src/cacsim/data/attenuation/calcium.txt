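# Mass attenuation coefficients mu/rho (cm^2/g) vs photon energy (keV)
# for calcium. Values follow the public NIST XCOM tabulation style on a
# coarse grid; interpolate log-log. Nominal density: 1.55 g/cm^3.
# energy_keV  mu_over_rho_cm2_per_g
10         93.41
15         29.71
20         13.06
30         4.08
40         1.83
50         1.019
60         0.6578
80         0.3656
100        0.2564
150        0.1674
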