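# Relative photon fluence per 1 keV bin for a tungsten-anode tube at 120 kV,
# filtered-Kramers bremsstrahlung model with 6.0 mm Al inherent filtration.
# energy_keV  relative_fluence
10.0     4.877443e-18
11.0     1.426765e-13
12.0     1.821763e-10
13.0     3.058681e-08
14.0     1.316430e-06
15.0     2.211265e-05
16.0     1.867816e-04
17.0     9.801628e-04
18.0     3.615632e-03
19.0     1.022757e-02
20.0     2.361528e-02
21.0     4.483070e-02
22.0     7.605663e-02
23.0     1.179437e-01
24.0     1.701044e-01
25.0     2.312640e-01
26.0     2.995334e-01
27.0     3.727074e-01
28.0     4.485262e-01
29.0     5.248709e-01
30.0     5.998865e-01
31.0     6.585301e-01
32.0     7.133738e-01
33.0     7.639511e-01
34.0     8.099740e-01
35.0     8.513026e-01
36.0     8.879167e-01
37.0     9.198894e-01
38.0     9.473638e-01
39.0     9.705339e-01
40.0     9.896285e-01
41.0     9.955445e-01
42.0     9.989303e-01
43.0     1.000000e+00
44.0     9.989577e-01
45.0     9.959961e-01
46.0     9.912963e-01
47.0     9.850273e-01
48.0     9.773465e-01
49.0     9.683994e-01
50.0     9.583207e-01
51.0     9.428790e-01
52.0     9.270381e-01
53.0     9.108606e-01
54.0     8.944028e-01
55.0     8.777158e-01
56.0     8.608457e-01
57.0     8.438337e-01
58.0     8.267173e-01
59.0     8.095298e-01
60.0     7.923015e-01
61.0     7.726235e-01
62.0     7.532105e-01
63.0     7.340636e-01
64.0     7.151833e-01
65.0     6.965695e-01
66.0     6.782213e-01
67.0     6.601378e-01
68.0     6.423171e-01
69.0     6.247574e-01
70.0     6.074565e-01
71.0     5.904118e-01
72.0     5.736205e-01
73.0     5.570797e-01
74.0     5.407864e-01
75.0     5.247372e-01
76.0     5.089289e-01
77.0     4.933579e-01
78.0     4.780208e-01
79.0     4.629141e-01
80.0     4.480341e-01
81.0     4.327635e-01
82.0     4.177748e-01
83.0     4.030603e-01
84.0     3.886125e-01
85.0     3.744243e-01
86.0     3.604887e-01
87.0     3.467991e-01
88.0     3.333491e-01
89.0     3.201324e-01
90.0     3.071430e-01
91.0     2.943751e-01
92.0     2.818231e-01
93.0     2.694815e-01
94.0     2.573451e-01
95.0     2.454088e-01
96.0     2.336677e-01
97.0     2.221170e-01
98.0     2.107521e-01
99.0     1.995686e-01
100.0    1.885622e-01
101.0    1.776150e-01
102.0    1.668527e-01
103.0    1.562705e-01
104.0    1.458638e-01
105.0    1.356282e-01
106.0    1.255592e-01
107.0    1.156528e-01
108.0    1.059049e-01
109.0    9.631173e-02
110.0    8.686941e-02
111.0    7.757435e-02
112.0    6.842303e-02
113.0    5.941203e-02
114.0    5.053808e-02
115.0    4.179796e-02
116.0    3.318859e-02
117.0    2.470697e-02
118.0    1.635020e-02
119.0    8.115452e-03
120.0    0.000000e+00
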