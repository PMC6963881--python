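block,factor,value,t_R,area,k_prime,n_plates,asymmetry,pct_t_R,pct_area,pct_k_prime,pct_n_plates,pct_asymmetry
temperature,column_temperature_C,23,15.44,2410869,6.78,4135,0.83,0.06,-0.87,4.15,1.22,1.22
temperature,column_temperature_C,25,15.43,2432036,6.51,4085,0.82,,,,,
temperature,column_temperature_C,27,15.57,2409197,6.92,4127,0.86,0.91,-0.94,6.30,1.03,4.88
flow,flow_rate_mL_min,0.9,15.15,2356539,7.02,3760,0.86,-1.81,-3.10,7.83,-7.96,4.88
flow,flow_rate_mL_min,1.0,15.43,2432036,6.51,4085,0.82,,,,,
flow,flow_rate_mL_min,1.1,15.84,2368076,6.47,3984,0.85,2.66,-2.63,-0.61,-2.47,3.66
composition,tpn_composition,ST,15.43,2432036,6.51,4085,0.82,,,,,
composition,tpn_composition,HEN,15.33,2342875,6.45,4321,0.84,-0.65,-3.67,-0.92,5.78,2.44
composition,tpn_composition,HEL,15.51,2401008,6.92,3981,0.83,0.52,-1.28,6.30,-2.55,1.22
composition,tpn_composition,LEL,15.50,2408139,7.13,4123,0.86,0.45,-0.98,9.52,0.93,4.88
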