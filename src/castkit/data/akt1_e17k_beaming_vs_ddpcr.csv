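level_expected_maf_pct,method_a_maf_pct,method_b_maf_pct,replicate_index,call
0,0.04,0.004,1,not_detected
0,0.04,0.003,2,not_detected
0,0.04,0.003,3,not_detected
0.05,0.06,0.05,1,detected
0.05,0.06,0.03,2,detected
0.05,0.06,0.03,3,detected
0.5,0.6,0.34,1,detected
0.5,0.6,0.30,2,detected
0.5,0.6,0.36,3,detected
1.0,1.0,0.75,1,detected
1.0,1.0,0.67,2,detected
1.0,1.0,0.65,3,detected
2.0,2.4,1.20,1,detected
2.0,2.4,1.55,2,detected
2.0,2.4,1.81,3,detected
5.0,5.4,3.01,1,detected
5.0,5.4,3.66,2,detected
5.0,5.4,4.29,3,detected
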