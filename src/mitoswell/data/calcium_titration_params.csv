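ca_uM,tau_min,a,k,err
40,25.7510,0.1174,0.7341,1.7233e-03
50,18.0899,0.1882,0.7370,8.5859e-04
60,15.4921,0.1965,0.7362,7.6069e-04
70,13.7992,0.2257,0.7442,1.3933e-03
80,7.1833,0.3194,0.7657,2.5434e-03
90,6.5893,0.3734,0.7971,3.7028e-03
100,2.2030,0.3182,0.7831,4.5558e-03
110,2.0000,0.3660,0.8596,5.4100e-03
120,2.0000,0.3513,0.8854,5.7481e-03
130,1.9999,0.3967,0.9300,6.9423e-03
140,1.8418,0.4554,0.9694,8.5506e-03
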