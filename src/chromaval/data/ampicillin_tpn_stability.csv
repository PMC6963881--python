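time_h,series,mean_content_pct,sd_pct
0,HEN,100.00,1.42
24,HEN,92.15,1.44
48,HEN,86.15,2.15
72,HEN,83.14,2.03
96,HEN,79.83,2.14
120,HEN,74.71,2.21
144,HEN,70.37,0.92
0,HEL,100.00,1.60
24,HEL,87.28,2.08
48,HEL,81.38,2.19
72,HEL,65.46,2.82
96,HEL,59.00,1.54
120,HEL,53.82,2.07
144,HEL,51.67,2.88
0,LEL,100.00,2.07
24,LEL,81.90,3.03
48,LEL,75.49,2.15
72,LEL,70.70,2.68
96,LEL,65.21,1.36
120,LEL,61.15,1.68
144,LEL,56.91,0.47
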