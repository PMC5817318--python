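# mass attenuation coefficients (cm^2/g)
# material: air  Z/A=0.49919  Z_eff=7.64
# energy_keV mu_pe mu_compton mu_rayleigh
10.0 5.249270e+00 1.925377e-01 2.727661e-01
11.0 3.724648e+00 1.918324e-01 2.275853e-01
12.0 2.722993e+00 1.911339e-01 1.929061e-01
13.0 2.041281e+00 1.904421e-01 1.656906e-01
14.0 1.563284e+00 1.897569e-01 1.439286e-01
15.0 1.219468e+00 1.890782e-01 1.262458e-01
16.0 9.666450e-01 1.884059e-01 1.116766e-01
17.0 7.771106e-01 1.877398e-01 9.952619e-02
18.0 6.325836e-01 1.870801e-01 8.928378e-02
19.0 5.206981e-01 1.864264e-01 8.056724e-02
20.0 4.329034e-01 1.857788e-01 7.308585e-02
21.0 3.631696e-01 1.851372e-01 6.661525e-02
22.0 3.071689e-01 1.845014e-01 6.097997e-02
23.0 2.617452e-01 1.838715e-01 5.604120e-02
24.0 2.245631e-01 1.832473e-01 5.168791e-02
25.0 1.938719e-01 1.826288e-01 4.783043e-02
26.0 1.683429e-01 1.820158e-01 4.439571e-02
27.0 1.469567e-01 1.814083e-01 4.132370e-02
28.0 1.289229e-01 1.808063e-01 3.856471e-02
29.0 1.136230e-01 1.802096e-01 3.607731e-02
30.0 1.005686e-01 1.796182e-01 3.382672e-02
31.0 8.937105e-02 1.790320e-01 3.178360e-02
32.0 7.971848e-02 1.784509e-01 2.992302e-02
33.0 7.135900e-02 1.778750e-01 2.822369e-02
34.0 6.408772e-02 1.773040e-01 2.666738e-02
35.0 5.773697e-02 1.767380e-01 2.523835e-02
36.0 5.216869e-02 1.761768e-01 2.392300e-02
37.0 4.726860e-02 1.756205e-01 2.270947e-02
38.0 4.294158e-02 1.750690e-01 2.158746e-02
39.0 3.910807e-02 1.745221e-01 2.054791e-02
40.0 3.570121e-02 1.739798e-01 1.958287e-02
41.0 3.266458e-02 1.734422e-01 1.868534e-02
42.0 2.995032e-02 1.729090e-01 1.784911e-02
43.0 2.751772e-02 1.723803e-01 1.706869e-02
44.0 2.533199e-02 1.718561e-01 1.633918e-02
45.0 2.336328e-02 1.713361e-01 1.565621e-02
46.0 2.158593e-02 1.708205e-01 1.501587e-02
47.0 1.997775e-02 1.703091e-01 1.441466e-02
48.0 1.851955e-02 1.698019e-01 1.384943e-02
49.0 1.719464e-02 1.692988e-01 1.331735e-02
50.0 1.598847e-02 1.687998e-01 1.281585e-02
51.0 1.488834e-02 1.683048e-01 1.234261e-02
52.0 1.388311e-02 1.678139e-01 1.189553e-02
53.0 1.296301e-02 1.673268e-01 1.147271e-02
54.0 1.211941e-02 1.668437e-01 1.107241e-02
55.0 1.134471e-02 1.663644e-01 1.069304e-02
56.0 1.063217e-02 1.658888e-01 1.033316e-02
57.0 9.975840e-03 1.654171e-01 9.991440e-03
58.0 9.370401e-03 1.649490e-01 9.666675e-03
59.0 8.811132e-03 1.644846e-01 9.357751e-03
60.0 8.293817e-03 1.640238e-01 9.063646e-03
61.0 7.814686e-03 1.635666e-01 8.783420e-03
62.0 7.370363e-03 1.631129e-01 8.516205e-03
63.0 6.957817e-03 1.626627e-01 8.261203e-03
64.0 6.574323e-03 1.622160e-01 8.017674e-03
65.0 6.217429e-03 1.617727e-01 7.784934e-03
66.0 5.884923e-03 1.613327e-01 7.562351e-03
67.0 5.574805e-03 1.608960e-01 7.349338e-03
68.0 5.285266e-03 1.604627e-01 7.145348e-03
69.0 5.014668e-03 1.600326e-01 6.949876e-03
70.0 4.761524e-03 1.596057e-01 6.762450e-03
71.0 4.524482e-03 1.591820e-01 6.582630e-03
72.0 4.302313e-03 1.587615e-01 6.410008e-03
73.0 4.093895e-03 1.583440e-01 6.244201e-03
74.0 3.898206e-03 1.579296e-01 6.084853e-03
75.0 3.714312e-03 1.575183e-01 5.931628e-03
76.0 3.541360e-03 1.571100e-01 5.784216e-03
77.0 3.378565e-03 1.567046e-01 5.642323e-03
78.0 3.225213e-03 1.563021e-01 5.505675e-03
79.0 3.080643e-03 1.559026e-01 5.374015e-03
80.0 2.944252e-03 1.555060e-01 5.247100e-03
81.0 2.815483e-03 1.551121e-01 5.124704e-03
82.0 2.693823e-03 1.547211e-01 5.006613e-03
83.0 2.578801e-03 1.543329e-01 4.892625e-03
84.0 2.469980e-03 1.539474e-01 4.782552e-03
85.0 2.366959e-03 1.535646e-01 4.676214e-03
86.0 2.269366e-03 1.531845e-01 4.573443e-03
87.0 2.176856e-03 1.528071e-01 4.474080e-03
88.0 2.089110e-03 1.524323e-01 4.377975e-03
89.0 2.005834e-03 1.520601e-01 4.284985e-03
90.0 1.926752e-03 1.516904e-01 4.194977e-03
91.0 1.851612e-03 1.513233e-01 4.107823e-03
92.0 1.780175e-03 1.509588e-01 4.023402e-03
93.0 1.712223e-03 1.505967e-01 3.941602e-03
94.0 1.647550e-03 1.502371e-01 3.862312e-03
95.0 1.585966e-03 1.498799e-01 3.785432e-03
96.0 1.527294e-03 1.495251e-01 3.710864e-03
97.0 1.471366e-03 1.491727e-01 3.638514e-03
98.0 1.418029e-03 1.488227e-01 3.568295e-03
99.0 1.367138e-03 1.484750e-01 3.500124e-03
100.0 1.318557e-03 1.481297e-01 3.433921e-03
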