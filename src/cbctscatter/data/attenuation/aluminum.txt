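# mass attenuation coefficients (cm^2/g)
# material: aluminum  Z/A=0.48181  Z_eff=13.0
# energy_keV mu_pe mu_compton mu_rayleigh
10.0 3.956662e+01 1.858342e-01 7.488681e-01
11.0 2.807471e+01 1.851535e-01 6.248262e-01
12.0 2.052468e+01 1.844793e-01 5.296158e-01
13.0 1.538625e+01 1.838116e-01 4.548969e-01
14.0 1.178333e+01 1.831503e-01 3.951501e-01
15.0 9.191796e+00 1.824952e-01 3.466027e-01
16.0 7.286131e+00 1.818462e-01 3.066037e-01
17.0 5.857507e+00 1.812034e-01 2.732451e-01
18.0 4.768128e+00 1.805666e-01 2.451250e-01
19.0 3.924786e+00 1.799357e-01 2.211941e-01
20.0 3.263029e+00 1.793107e-01 2.006542e-01
21.0 2.737408e+00 1.786914e-01 1.828894e-01
22.0 2.315300e+00 1.780778e-01 1.674180e-01
23.0 1.972917e+00 1.774698e-01 1.538588e-01
24.0 1.692655e+00 1.768673e-01 1.419070e-01
25.0 1.461319e+00 1.762703e-01 1.313165e-01
26.0 1.268893e+00 1.756787e-01 1.218866e-01
27.0 1.107693e+00 1.750923e-01 1.134525e-01
28.0 9.717622e-01 1.745113e-01 1.058778e-01
29.0 8.564384e-01 1.739353e-01 9.904878e-02
30.0 7.580405e-01 1.733645e-01 9.286989e-02
31.0 6.736384e-01 1.727987e-01 8.726058e-02
32.0 6.008817e-01 1.722379e-01 8.215242e-02
33.0 5.378718e-01 1.716820e-01 7.748700e-02
34.0 4.830642e-01 1.711309e-01 7.321421e-02
35.0 4.351951e-01 1.705846e-01 6.929087e-02
36.0 3.932239e-01 1.700430e-01 6.567961e-02
37.0 3.562892e-01 1.695060e-01 6.234793e-02
38.0 3.236741e-01 1.689737e-01 5.926748e-02
39.0 2.947789e-01 1.684458e-01 5.641344e-02
40.0 2.690995e-01 1.679225e-01 5.376397e-02
41.0 2.462108e-01 1.674035e-01 5.129984e-02
42.0 2.257519e-01 1.668890e-01 4.900401e-02
43.0 2.074161e-01 1.663787e-01 4.686140e-02
44.0 1.909410e-01 1.658727e-01 4.485855e-02
45.0 1.761018e-01 1.653708e-01 4.298348e-02
46.0 1.627049e-01 1.648731e-01 4.122545e-02
47.0 1.505832e-01 1.643795e-01 3.957486e-02
48.0 1.395920e-01 1.638900e-01 3.802305e-02
49.0 1.296054e-01 1.634044e-01 3.656224e-02
50.0 1.205138e-01 1.629228e-01 3.518538e-02
51.0 1.122216e-01 1.624451e-01 3.388613e-02
52.0 1.046446e-01 1.619712e-01 3.265870e-02
53.0 9.770928e-02 1.615011e-01 3.149787e-02
54.0 9.135060e-02 1.610348e-01 3.039885e-02
55.0 8.551125e-02 1.605721e-01 2.935731e-02
56.0 8.014050e-02 1.601132e-01 2.836926e-02
57.0 7.519335e-02 1.596578e-01 2.743109e-02
58.0 7.062983e-02 1.592061e-01 2.653946e-02
59.0 6.641431e-02 1.587578e-01 2.569132e-02
60.0 6.251503e-02 1.583131e-01 2.488387e-02
61.0 5.890356e-02 1.578718e-01 2.411452e-02
62.0 5.555445e-02 1.574339e-01 2.338089e-02
63.0 5.244486e-02 1.569994e-01 2.268079e-02
64.0 4.955426e-02 1.565682e-01 2.201220e-02
65.0 4.686416e-02 1.561403e-01 2.137322e-02
66.0 4.435788e-02 1.557157e-01 2.076213e-02
67.0 4.202035e-02 1.552942e-01 2.017731e-02
68.0 3.983794e-02 1.548760e-01 1.961726e-02
69.0 3.779829e-02 1.544608e-01 1.908060e-02
70.0 3.589021e-02 1.540488e-01 1.856603e-02
71.0 3.410349e-02 1.536399e-01 1.807234e-02
72.0 3.242888e-02 1.532340e-01 1.759842e-02
73.0 3.085792e-02 1.528311e-01 1.714320e-02
74.0 2.938291e-02 1.524311e-01 1.670571e-02
75.0 2.799680e-02 1.520341e-01 1.628504e-02
76.0 2.669316e-02 1.516400e-01 1.588033e-02
77.0 2.546609e-02 1.512487e-01 1.549077e-02
78.0 2.431019e-02 1.508603e-01 1.511561e-02
79.0 2.322049e-02 1.504746e-01 1.475414e-02
80.0 2.219244e-02 1.500918e-01 1.440570e-02
81.0 2.122183e-02 1.497117e-01 1.406967e-02
82.0 2.030482e-02 1.493343e-01 1.374545e-02
83.0 1.943783e-02 1.489596e-01 1.343250e-02
84.0 1.861759e-02 1.485875e-01 1.313030e-02
85.0 1.784107e-02 1.482180e-01 1.283835e-02
86.0 1.710545e-02 1.478512e-01 1.255620e-02
87.0 1.640815e-02 1.474869e-01 1.228340e-02
88.0 1.574676e-02 1.471251e-01 1.201955e-02
89.0 1.511906e-02 1.467659e-01 1.176425e-02
90.0 1.452299e-02 1.464091e-01 1.151714e-02
91.0 1.395661e-02 1.460548e-01 1.127786e-02
92.0 1.341815e-02 1.457029e-01 1.104609e-02
93.0 1.290596e-02 1.453534e-01 1.082151e-02
94.0 1.241849e-02 1.450063e-01 1.060382e-02
95.0 1.195429e-02 1.446616e-01 1.039275e-02
96.0 1.151205e-02 1.443192e-01 1.018802e-02
97.0 1.109049e-02 1.439791e-01 9.989391e-03
98.0 1.068846e-02 1.436413e-01 9.796609e-03
99.0 1.030486e-02 1.433057e-01 9.609448e-03
100.0 9.938685e-03 1.429723e-01 9.427690e-03
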