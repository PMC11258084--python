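# Relative photon fluence per 1 keV bin for a tungsten-anode tube at 80 kV,
# filtered-Kramers bremsstrahlung model with 6.0 mm Al inherent filtration.
# energy_keV  relative_fluence
10.0     6.272712e-18
11.0     1.825293e-13
12.0     2.318115e-10
13.0     3.870643e-08
14.0     1.656508e-06
15.0     2.766449e-05
16.0     2.322943e-04
17.0     1.211600e-03
18.0     4.441539e-03
19.0     1.248356e-02
20.0     2.863532e-02
21.0     5.399457e-02
22.0     9.096971e-02
23.0     1.400670e-01
24.0     2.005349e-01
25.0     2.705857e-01
26.0     3.477515e-01
27.0     4.292583e-01
28.0     5.123434e-01
29.0     5.944825e-01
30.0     6.735260e-01
31.0     7.327225e-01
32.0     7.863820e-01
33.0     8.340690e-01
34.0     8.755647e-01
35.0     9.108258e-01
36.0     9.399471e-01
37.0     9.631275e-01
38.0     9.806409e-01
39.0     9.928127e-01
40.0     1.000000e+00
41.0     9.932441e-01
42.0     9.835172e-01
43.0     9.711108e-01
44.0     9.562992e-01
45.0     9.393387e-01
46.0     9.204675e-01
47.0     8.999060e-01
48.0     8.778571e-01
49.0     8.545071e-01
50.0     8.300263e-01
51.0     8.008712e-01
52.0     7.714442e-01
53.0     7.418202e-01
54.0     7.120662e-01
55.0     6.822419e-01
56.0     6.524006e-01
57.0     6.225897e-01
58.0     5.928513e-01
59.0     5.632227e-01
60.0     5.337367e-01
61.0     5.028371e-01
62.0     4.724095e-01
63.0     4.424514e-01
64.0     4.129592e-01
65.0     3.839289e-01
66.0     3.553559e-01
67.0     3.272351e-01
68.0     2.995609e-01
69.0     2.723277e-01
70.0     2.455291e-01
71.0     2.191590e-01
72.0     1.932107e-01
73.0     1.676777e-01
74.0     1.425532e-01
75.0     1.178303e-01
76.0     9.350228e-02
77.0     6.956210e-02
78.0     4.600291e-02
79.0     2.281783e-02
80.0     0.000000e+00
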