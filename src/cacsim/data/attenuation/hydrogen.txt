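# Mass attenuation coefficients mu/rho (cm^2/g) vs photon energy (keV)
# for hydrogen. Values follow the public NIST XCOM tabulation style on a
# coarse grid; interpolate log-log. Nominal density: 8.99e-05 g/cm^3.
# energy_keV  mu_over_rho_cm2_per_g
10         0.3854
15         0.3764
20         0.3695
30         0.357
40         0.3458
50         0.3355
60         0.326
80         0.3091
100        0.2944
150        0.2651
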