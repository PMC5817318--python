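# mass attenuation coefficients (cm^2/g)
# material: bone  Z/A=0.5213  Z_eff=13.8
# energy_keV mu_pe mu_compton mu_rayleigh
10.0 4.964605e+01 2.010655e-01 8.388479e-01
11.0 3.522663e+01 2.003290e-01 6.999018e-01
12.0 2.575326e+01 1.995996e-01 5.932515e-01
13.0 1.930584e+01 1.988771e-01 5.095547e-01
14.0 1.478508e+01 1.981616e-01 4.426291e-01
15.0 1.153337e+01 1.974528e-01 3.882485e-01
16.0 9.142243e+00 1.967507e-01 3.434435e-01
17.0 7.349683e+00 1.960552e-01 3.060767e-01
18.0 5.982789e+00 1.953662e-01 2.745778e-01
19.0 4.924609e+00 1.946836e-01 2.477715e-01
20.0 4.094272e+00 1.940073e-01 2.247637e-01
21.0 3.434751e+00 1.933372e-01 2.048644e-01
22.0 2.905113e+00 1.926733e-01 1.875340e-01
23.0 2.475509e+00 1.920155e-01 1.723456e-01
24.0 2.123852e+00 1.913637e-01 1.589578e-01
25.0 1.833583e+00 1.907177e-01 1.470948e-01
26.0 1.592138e+00 1.900776e-01 1.365318e-01
27.0 1.389873e+00 1.894432e-01 1.270843e-01
28.0 1.219315e+00 1.888145e-01 1.185995e-01
29.0 1.074613e+00 1.881914e-01 1.109499e-01
30.0 9.511482e-01 1.875738e-01 1.040286e-01
31.0 8.452450e-01 1.869616e-01 9.774532e-02
32.0 7.539539e-01 1.863548e-01 9.202339e-02
33.0 6.748924e-01 1.857534e-01 8.679740e-02
34.0 6.061228e-01 1.851571e-01 8.201122e-02
35.0 5.460592e-01 1.845660e-01 7.761648e-02
36.0 4.933961e-01 1.839800e-01 7.357130e-02
37.0 4.470525e-01 1.833991e-01 6.983931e-02
38.0 4.061288e-01 1.828231e-01 6.638873e-02
39.0 3.698726e-01 1.822520e-01 6.319176e-02
40.0 3.376515e-01 1.816857e-01 6.022395e-02
41.0 3.089320e-01 1.811242e-01 5.746374e-02
42.0 2.832613e-01 1.805675e-01 5.489206e-02
43.0 2.602545e-01 1.800154e-01 5.249200e-02
44.0 2.395825e-01 1.794679e-01 5.024850e-02
45.0 2.209631e-01 1.789249e-01 4.814813e-02
46.0 2.041534e-01 1.783864e-01 4.617887e-02
47.0 1.889437e-01 1.778524e-01 4.432995e-02
48.0 1.751525e-01 1.773227e-01 4.259169e-02
49.0 1.626218e-01 1.767973e-01 4.095535e-02
50.0 1.512142e-01 1.762762e-01 3.941306e-02
51.0 1.408095e-01 1.757593e-01 3.795770e-02
52.0 1.313024e-01 1.752466e-01 3.658279e-02
53.0 1.226003e-01 1.747380e-01 3.528248e-02
54.0 1.146218e-01 1.742335e-01 3.405141e-02
55.0 1.072949e-01 1.737329e-01 3.288472e-02
56.0 1.005560e-01 1.732363e-01 3.177796e-02
57.0 9.434855e-02 1.727437e-01 3.072706e-02
58.0 8.862249e-02 1.722549e-01 2.972830e-02
59.0 8.333309e-02 1.717699e-01 2.877825e-02
60.0 7.844047e-02 1.712887e-01 2.787378e-02
61.0 7.390900e-02 1.708113e-01 2.701199e-02
62.0 6.970672e-02 1.703375e-01 2.619021e-02
63.0 6.580498e-02 1.698674e-01 2.540599e-02
64.0 6.217801e-02 1.694008e-01 2.465706e-02
65.0 5.880261e-02 1.689378e-01 2.394131e-02
66.0 5.565787e-02 1.684784e-01 2.325679e-02
67.0 5.272486e-02 1.680224e-01 2.260170e-02
68.0 4.998649e-02 1.675699e-01 2.197436e-02
69.0 4.742725e-02 1.671207e-01 2.137322e-02
70.0 4.503309e-02 1.666749e-01 2.079682e-02
71.0 4.279122e-02 1.662325e-01 2.024381e-02
72.0 4.069000e-02 1.657933e-01 1.971294e-02
73.0 3.871885e-02 1.653574e-01 1.920303e-02
74.0 3.686808e-02 1.649246e-01 1.871298e-02
75.0 3.512887e-02 1.644951e-01 1.824176e-02
76.0 3.349313e-02 1.640686e-01 1.778842e-02
77.0 3.195348e-02 1.636453e-01 1.735205e-02
78.0 3.050311e-02 1.632250e-01 1.693181e-02
79.0 2.913582e-02 1.628078e-01 1.652691e-02
80.0 2.784587e-02 1.623936e-01 1.613661e-02
81.0 2.662801e-02 1.619823e-01 1.576020e-02
82.0 2.547738e-02 1.615740e-01 1.539703e-02
83.0 2.438954e-02 1.611685e-01 1.504648e-02
84.0 2.336035e-02 1.607660e-01 1.470796e-02
85.0 2.238600e-02 1.603662e-01 1.438094e-02
86.0 2.146299e-02 1.599693e-01 1.406488e-02
87.0 2.058806e-02 1.595752e-01 1.375931e-02
88.0 1.975819e-02 1.591838e-01 1.346375e-02
89.0 1.897058e-02 1.587951e-01 1.317778e-02
90.0 1.822266e-02 1.584091e-01 1.290097e-02
91.0 1.751200e-02 1.580257e-01 1.263294e-02
92.0 1.683637e-02 1.576450e-01 1.237332e-02
93.0 1.619370e-02 1.572669e-01 1.212176e-02
94.0 1.558204e-02 1.568913e-01 1.187792e-02
95.0 1.499960e-02 1.565183e-01 1.164148e-02
96.0 1.444469e-02 1.561478e-01 1.141216e-02
97.0 1.391575e-02 1.557799e-01 1.118966e-02
98.0 1.341130e-02 1.554143e-01 1.097371e-02
99.0 1.292998e-02 1.550513e-01 1.076407e-02
100.0 1.247052e-02 1.546906e-01 1.056047e-02
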