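compound_id,ALOGPS_logs,Mor29m,IC5,GAP_energy,IC50,logRA
1,-2.3500,-0.3050,4.8620,0.2616,97,0.0000
2,-3.5200,-0.3070,5.2530,0.2525,100,-0.0132
3,-6.3500,-0.4550,5.6840,0.2521,2.8,1.5396
4,-6.8400,-0.5250,5.6240,0.2524,1.2,1.9075
5,-7.1600,-0.5140,5.5010,0.2527,0.46,2.3240
6,-7.4900,-0.5010,5.2250,0.2525,4.2,1.3635
7,-3.6400,-0.2360,5.2170,0.2467,100,-0.0132
8,-7.0300,-0.5260,5.5970,0.2462,0.72,2.1294
9,-7.6800,-0.1790,5.1970,0.2462,100,-0.0132
10,-3.6800,-0.3650,5.2530,0.2367,100,-0.0132
11,-3.6800,-0.3050,5.2530,0.2359,100,-0.0132
12,-6.9700,-0.3940,5.5080,0.2457,2.8,1.5396
13,-6.9700,-0.2910,5.5080,0.2552,4.4,1.3433
14,-7.4000,-0.2280,5.1590,0.2217,100,-0.0132
15,-7.4000,-0.2280,5.1590,0.2287,100,-0.0132
16,-3.7500,-0.4430,5.1800,0.2194,100,-0.0132
17,-7.6100,-0.3330,5.1680,0.2177,100,-0.0132
18,-5.4900,-0.3470,5.6380,0.2199,42.3,0.3604
19,-6.7200,-0.5520,5.5430,0.2491,1.3,1.8728
20,-7.0600,-0.5520,5.4190,0.2492,0.77,2.1002
21,-6.8400,-0.5150,5.5160,0.2449,3.7,1.4185
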