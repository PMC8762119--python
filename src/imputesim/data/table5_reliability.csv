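software,reference_size,1,5,10,30,50,90
Beagle5.1,100,0.21,0.56,0.80,0.97,0.99,1.00
Beagle5.1,1000,0.25,0.78,0.94,0.99,1.00,1.00
Beagle5.1,3000,0.26,0.90,0.97,0.99,1.00,1.00
Beagle5.1,5000,0.26,0.94,0.98,1.00,1.00,1.00
Beagle5.1,10000,0.27,0.96,0.99,1.00,1.00,1.00
Minimac4,100,0.14,0.47,0.63,0.82,0.88,0.94
Minimac4,1000,0.20,0.58,0.72,0.86,0.90,0.95
Minimac4,3000,0.25,0.63,0.74,0.87,0.91,0.95
Minimac4,5000,0.28,0.64,0.75,0.87,0.91,0.95
Minimac4,10000,0.33,0.67,0.77,0.87,0.91,0.95
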