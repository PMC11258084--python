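# Relative photon fluence per 1 keV bin for a tungsten-anode tube at 135 kV,
# filtered-Kramers bremsstrahlung model with 6.0 mm Al inherent filtration.
# energy_keV  relative_fluence
10.0     4.633771e-18
11.0     1.356977e-13
12.0     1.734596e-10
13.0     2.915650e-08
14.0     1.256326e-06
15.0     2.112797e-05
16.0     1.786788e-04
17.0     9.387892e-04
18.0     3.467328e-03
19.0     9.820510e-03
20.0     2.270471e-02
21.0     4.315889e-02
22.0     7.331867e-02
23.0     1.138534e-01
24.0     1.644343e-01
25.0     2.238733e-01
26.0     2.903816e-01
27.0     3.618544e-01
28.0     4.361229e-01
29.0     5.111426e-01
30.0     5.851146e-01
31.0     6.433452e-01
32.0     6.980666e-01
33.0     7.488100e-01
34.0     7.952782e-01
35.0     8.373174e-01
36.0     8.748896e-01
37.0     9.080478e-01
38.0     9.369141e-01
39.0     9.616610e-01
40.0     9.824963e-01
41.0     9.903451e-01
42.0     9.957461e-01
43.0     9.989005e-01
44.0     1.000000e+00
45.0     9.992266e-01
46.0     9.967515e-01
47.0     9.927347e-01
48.0     9.873257e-01
49.0     9.806629e-01
50.0     9.728746e-01
51.0     9.596465e-01
52.0     9.460017e-01
53.0     9.320003e-01
54.0     9.176971e-01
55.0     9.031412e-01
56.0     8.883774e-01
57.0     8.734460e-01
58.0     8.583831e-01
59.0     8.432216e-01
60.0     8.279910e-01
61.0     8.101636e-01
62.0     7.925676e-01
63.0     7.752048e-01
64.0     7.580761e-01
65.0     7.411821e-01
66.0     7.245225e-01
67.0     7.080970e-01
68.0     6.919043e-01
69.0     6.759434e-01
70.0     6.602124e-01
71.0     6.447094e-01
72.0     6.294324e-01
73.0     6.143789e-01
74.0     5.995465e-01
75.0     5.849324e-01
76.0     5.705340e-01
77.0     5.563483e-01
78.0     5.423723e-01
79.0     5.286031e-01
80.0     5.150375e-01
81.0     5.009621e-01
82.0     4.871466e-01
83.0     4.735837e-01
84.0     4.602667e-01
85.0     4.471889e-01
86.0     4.343441e-01
87.0     4.217260e-01
88.0     4.093288e-01
89.0     3.971466e-01
90.0     3.851740e-01
91.0     3.734056e-01
92.0     3.618363e-01
93.0     3.504609e-01
94.0     3.392747e-01
95.0     3.282730e-01
96.0     3.174513e-01
97.0     3.068051e-01
98.0     2.963303e-01
99.0     2.860227e-01
100.0    2.758784e-01
101.0    2.657236e-01
102.0    2.557407e-01
103.0    2.459253e-01
104.0    2.362732e-01
105.0    2.267801e-01
106.0    2.174421e-01
107.0    2.082552e-01
108.0    1.992158e-01
109.0    1.903202e-01
110.0    1.815649e-01
111.0    1.729466e-01
112.0    1.644619e-01
113.0    1.561076e-01
114.0    1.478808e-01
115.0    1.397784e-01
116.0    1.317976e-01
117.0    1.239356e-01
118.0    1.161896e-01
119.0    1.085570e-01
120.0    1.010353e-01
121.0    9.362207e-02
122.0    8.631486e-02
123.0    7.911137e-02
124.0    7.200933e-02
125.0    6.500656e-02
126.0    5.810095e-02
127.0    5.129041e-02
128.0    4.457296e-02
129.0    3.794663e-02
130.0    3.140954e-02
131.0    2.495985e-02
132.0    1.859577e-02
133.0    1.231555e-02
134.0    6.117513e-03
135.0    0.000000e+00
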