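predicted_value,observed_value,observed_rank,experiment,medium,supplement,promoter,rbs
0.48,0.48,1,E17,M3,S0,P2,R5
0.48,0.48,1,E29,M3,S0,P4,R2
0.48,0.48,1,E45,M3,S0,P2,R3
1.08,1.68,2,E18,M3,S3,P2,R5
1.08,0.48,1,E52,M3,S0,P3,R2
1.08,1.68,3,E43,M3,S3,P2,R2
1.08,8.28,14,E64,M3,S3,P4,R4
1.68,0.48,1,E54,M3,S3,P3,R2
1.68,1.68,3,E53,M3,S1,P3,R2
1.68,5.28,9,E50,M3,S1,P2,R5
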