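software,reference_size,1,5,10,30,50,90
Beagle5.1,100,19.15,11.76,5.77,1.15,0.53,0.16
Beagle5.1,1000,18.44,6.55,1.91,0.43,0.23,0.09
Beagle5.1,3000,18.27,2.99,0.98,0.22,0.12,0.05
Beagle5.1,5000,18.20,2.03,0.68,0.15,0.08,0.04
Beagle5.1,10000,18.10,1.17,0.41,0.09,0.05,0.02
Minimac4,100,17.25,11.41,9.01,6.83,7.09,21.26
Minimac4,1000,16.36,10.80,8.64,6.79,7.24,23.31
Minimac4,3000,16.00,10.72,8.65,6.88,7.39,24.33
Minimac4,5000,15.85,10.70,8.68,6.93,7.46,24.80
Minimac4,10000,15.67,10.70,8.74,7.02,7.58,25.46
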