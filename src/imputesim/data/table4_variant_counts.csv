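proportion,P1,P2,P3,P4,density_snps_per_kb
total,212696,214899,216366,213389,21.4
0.01,2126,2148,2163,2133,0.2
0.05,10634,10744,10818,10669,1.1
0.1,21269,21489,21636,21338,2.1
0.3,63808,64469,64909,64016,6.4
0.5,106348,107449,108183,106694,10.7
0.9,191426,193409,194729,192050,19.3
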