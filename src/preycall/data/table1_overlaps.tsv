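gene	overlap_cases	total_cases
RPS8	177	755
RPL17	136	527
ARRB2	189	593
DCD	141	579
EIF3K	248	954
IGF2BP2	440	1729
IFIT3	192	965
KRT13	465	846
KRT36	458	825
KRT17	471	862
KRT4	188	757
BAG6	238	933
LRP2	395	1525
NPLOC4	425	1399
PSMF1	208	804
PDIA4	274	1211
RGS10	201	854
SNRPG	107	446
SF3B1	249	958
UGDH	143	481
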