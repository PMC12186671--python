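predicted_value,observed_value,observed_rank,experiment,medium,supplement,promoter,rbs
100,100,1,E25,M0,S2,P3,R4
95.83,87.03,3,E34,M0,S2,P1,R1
86.59,79.66,5,E28,M0,S1,P3,R5
75.47,54.12,7,E33,M0,S1,P1,R1
71.20,44.07,11,E20,M0,S3,P3,R1
69.28,63.03,6,E41,M0,S3,P1,R5
65.22,80.55,4,E31,M0,S2,P4,R4
60.31,42.49,12,E36,M0,S1,P1,R2
59.37,98.32,2,E48,M0,S3,P2,R5
53.70,40.06,10,E37,M0,S3,P1,R2
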