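# mass attenuation coefficients (cm^2/g)
# material: soft_tissue  Z/A=0.55509  Z_eff=7.42
# energy_keV mu_pe mu_compton mu_rayleigh
10.0 4.697632e+00 2.140983e-01 2.580360e-01
11.0 3.333231e+00 2.133141e-01 2.152952e-01
12.0 2.436837e+00 2.125374e-01 1.824887e-01
13.0 1.826766e+00 2.117681e-01 1.567429e-01
14.0 1.399001e+00 2.110062e-01 1.361561e-01
15.0 1.091316e+00 2.102514e-01 1.194282e-01
16.0 8.650617e-01 2.095038e-01 1.056458e-01
17.0 6.954452e-01 2.087632e-01 9.415154e-02
18.0 5.661063e-01 2.080295e-01 8.446224e-02
19.0 4.659787e-01 2.073027e-01 7.621642e-02
20.0 3.874102e-01 2.065826e-01 6.913904e-02
21.0 3.250046e-01 2.058691e-01 6.301787e-02
22.0 2.748890e-01 2.051622e-01 5.768691e-02
23.0 2.342388e-01 2.044617e-01 5.301484e-02
24.0 2.009641e-01 2.037676e-01 4.889664e-02
25.0 1.734982e-01 2.030798e-01 4.524747e-02
26.0 1.506520e-01 2.023982e-01 4.199823e-02
27.0 1.315132e-01 2.017227e-01 3.909212e-02
28.0 1.153746e-01 2.010532e-01 3.648212e-02
29.0 1.016825e-01 2.003897e-01 3.412905e-02
30.0 9.000000e-02 1.997321e-01 3.200000e-02
31.0 7.997918e-02 1.990802e-01 3.006721e-02
32.0 7.134099e-02 1.984341e-01 2.830710e-02
33.0 6.385999e-02 1.977937e-01 2.669955e-02
34.0 5.735284e-02 1.971587e-01 2.522728e-02
35.0 5.166948e-02 1.965293e-01 2.387542e-02
36.0 4.668636e-02 1.959054e-01 2.263110e-02
37.0 4.230121e-02 1.952868e-01 2.148311e-02
38.0 3.842891e-02 1.946734e-01 2.042168e-02
39.0 3.499826e-02 1.940653e-01 1.943827e-02
40.0 3.194943e-02 1.934624e-01 1.852535e-02
41.0 2.923191e-02 1.928645e-01 1.767629e-02
42.0 2.680289e-02 1.922716e-01 1.688522e-02
43.0 2.462593e-02 1.916837e-01 1.614694e-02
44.0 2.266989e-02 1.911007e-01 1.545682e-02
45.0 2.090807e-02 1.905226e-01 1.481073e-02
46.0 1.931750e-02 1.899492e-01 1.420498e-02
47.0 1.787832e-02 1.893805e-01 1.363623e-02
48.0 1.657336e-02 1.888165e-01 1.310153e-02
49.0 1.538768e-02 1.882571e-01 1.259818e-02
50.0 1.430827e-02 1.877022e-01 1.212376e-02
51.0 1.332375e-02 1.871518e-01 1.167608e-02
52.0 1.242416e-02 1.866059e-01 1.125315e-02
53.0 1.160075e-02 1.860643e-01 1.085316e-02
54.0 1.084580e-02 1.855271e-01 1.047447e-02
55.0 1.015251e-02 1.849941e-01 1.011559e-02
56.0 9.514854e-03 1.844653e-01 9.775143e-03
57.0 8.927494e-03 1.839407e-01 9.451879e-03
58.0 8.385679e-03 1.834202e-01 9.144652e-03
59.0 7.885183e-03 1.829038e-01 8.852410e-03
60.0 7.422232e-03 1.823914e-01 8.574188e-03
61.0 6.993452e-03 1.818830e-01 8.309094e-03
62.0 6.595822e-03 1.813785e-01 8.056310e-03
63.0 6.226630e-03 1.808779e-01 7.815078e-03
64.0 5.883437e-03 1.803812e-01 7.584700e-03
65.0 5.564049e-03 1.798882e-01 7.364529e-03
66.0 5.266485e-03 1.793989e-01 7.153966e-03
67.0 4.988957e-03 1.789134e-01 6.952456e-03
68.0 4.729845e-03 1.784315e-01 6.759482e-03
69.0 4.487684e-03 1.779533e-01 6.574566e-03
70.0 4.261143e-03 1.774786e-01 6.397261e-03
71.0 4.049011e-03 1.770075e-01 6.227152e-03
72.0 3.850189e-03 1.765398e-01 6.063852e-03
73.0 3.663673e-03 1.760756e-01 5.906999e-03
74.0 3.488549e-03 1.756148e-01 5.756256e-03
75.0 3.323981e-03 1.751574e-01 5.611306e-03
76.0 3.169203e-03 1.747034e-01 5.471854e-03
77.0 3.023517e-03 1.742526e-01 5.337624e-03
78.0 2.886280e-03 1.738051e-01 5.208355e-03
79.0 2.756903e-03 1.733608e-01 5.083805e-03
80.0 2.634845e-03 1.729197e-01 4.963744e-03
81.0 2.519608e-03 1.724818e-01 4.847958e-03
82.0 2.410733e-03 1.720470e-01 4.736244e-03
83.0 2.307799e-03 1.716153e-01 4.628412e-03
84.0 2.210414e-03 1.711866e-01 4.524283e-03
85.0 2.118219e-03 1.707610e-01 4.423687e-03
86.0 2.030882e-03 1.703383e-01 4.326466e-03
87.0 1.948093e-03 1.699186e-01 4.232469e-03
88.0 1.869569e-03 1.695018e-01 4.141554e-03
89.0 1.795044e-03 1.690880e-01 4.053586e-03
90.0 1.724273e-03 1.686769e-01 3.968438e-03
91.0 1.657029e-03 1.682687e-01 3.885990e-03
92.0 1.593099e-03 1.678633e-01 3.806129e-03
93.0 1.532288e-03 1.674607e-01 3.728746e-03
94.0 1.474412e-03 1.670608e-01 3.653738e-03
95.0 1.419299e-03 1.666636e-01 3.581010e-03
96.0 1.366793e-03 1.662692e-01 3.510468e-03
97.0 1.316742e-03 1.658773e-01 3.442025e-03
98.0 1.269010e-03 1.654881e-01 3.375599e-03
99.0 1.223467e-03 1.651015e-01 3.311109e-03
100.0 1.179992e-03 1.647174e-01 3.248481e-03
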