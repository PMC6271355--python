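compound_id,ALOGPS_logs,Mor29m,IC5,GAP_energy
22,-5.030000,-0.412000,5.514000,0.252200
23,-5.760000,-0.443000,5.628000,0.252200
24,-7.390000,-0.515000,5.364000,0.252400
25,-7.140100,-0.305100,5.571100,0.219700
26,-6.030000,-0.311000,5.572000,0.252400
27,-4.820000,-0.518000,5.856000,0.251700
28,-7.350000,-0.601000,5.280000,0.227600
29,-7.010000,-0.543000,5.488000,0.232300
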