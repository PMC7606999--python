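# Synthetic Ir-192-like HDR source characterization (NOT a measured dataset).
# Dose-rate constant in Gy/h/U; air-kerma strength in U (~10 Ci source); radii in cm.
dose_rate_constant,0.01109
air_kerma_strength,40800.0
r_min,0.1
r_max,10.0
[radial_dose]
r_cm,g
0.1,0.990
0.25,0.994
0.5,0.998
0.75,0.999
1.0,1.000
1.5,1.000
2.0,0.998
2.5,0.996
3.0,0.993
4.0,0.987
5.0,0.978
6.0,0.967
8.0,0.937
10.0,0.897
[anisotropy]
r_cm,phi_an
0.1,0.920
0.25,0.934
0.5,0.944
0.75,0.950
1.0,0.955
1.5,0.959
2.0,0.962
2.5,0.964
3.0,0.966
4.0,0.969
5.0,0.971
6.0,0.972
8.0,0.974
10.0,0.975
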