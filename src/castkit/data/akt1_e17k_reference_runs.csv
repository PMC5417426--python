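material,maf_percent,copies_per_ml,run_1,run_2,run_3,run_4,run_5,run_6,run_7,run_8,run_9,run_10,run_11
high_quality,50,200000,-4.98,-4.77,-4.16,-4.38,-4.33,-4.44,-4.41,-4.67,-4.28,-4.45,-4.39
high_quality,10,200000,-7.36,-7.08,-6.63,-6.71,-6.19,-6.50,-6.54,-6.63,-6.60,-6.70,-6.46
high_quality,5,200000,-8.02,-7.89,-7.57,-7.77,-7.55,-7.44,-7.60,-7.83,-7.76,-7.86,-7.99
high_quality,2,200000,-8.82,-8.35,-8.15,-9.30,-8.45,-8.62,-9.06,-8.02,-8.42,-8.91,-8.59
high_quality,1,200000,-9.98,-10.25,-9.82,-8.73,-8.88,-8.99,-8.87,-9.82,-9.66,-9.00,-9.37
high_quality,0,200000,-,-,-15.53,-,-,-,-,-,-15.16,-,-15.45
high_quality,0,2000000,-,-18.81,-15.50,-17.43,-18.00,-16.77,-16.50,-16.41,-19.36,-15.12,-20.66
ffpe,50,200000,–4.64,–4.43,–5.90,–4.58,–4.83,–4.86,–4.72,–4.64,–4.45,–4.91,–3.77
ffpe,10,200000,–8.13,–5.83,–7.11,–5.53,–6.50,–5.36,–8.32,–4.28,–4.56,–7.52,–6.53
ffpe,5,200000,–5.81,–9.50,–5.09,–9.81,–6.81,–10.65,–6.17,–5.50,–5.86,–6.40,–8.66
ffpe,2,200000,–9.62,–8.64,-,–6.68,-,–7.02,–4.71,–4.92,-,-,–5.77
ffpe,1,200000,-,–9.09,–9.27,-,–3.01,–6.39,-,-,–6.59,–5.74,-
ffpe,0,200000,-,-,-,-,-,-,-,-,-,-,-
ffpe,0,2000000,-,-,-,-,-9.16,-11.03,-,-,-,-,-
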