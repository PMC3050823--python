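generation,kg,p_below_0,p_below_2
1,1.25,2.08623744e-10,0.9999124827
2,2.09,7.985402526e-14,0.3791384628
3,2.65,1.040790414e-14,0.03060447704
4,3.02,1.98412662e-14,0.005203109091
5,3.28,1.170051682e-13,0.00214753567
6,3.45,1.000003486e-12,0.001578612433
7,3.56,8.66702979e-12,0.001603150223
8,3.64,6.518620135e-11,0.001918852326
9,3.69,4.021622292e-10,0.002471397125
10,3.72,2.01741125e-09,0.003259343564
11,3.74,8.331779166e-09,0.004289653215
12,3.76,2.891668289e-08,0.005564491752
13,3.77,8.623887625e-08,0.007077818023
14,3.78,2.257283997e-07,0.008815925854
15,3.78,5.284405163e-07,0.0107595171
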