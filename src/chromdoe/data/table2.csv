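run_id,methanol_initial,methanol_final,gradient_duration,t_e_imp_x,t_b_imp_III,t_imp_V,W_USP,t_range
1,35,75,17.5,15.00,15.03,17.21,0.24,12.405
2,40,75,17.5,13.66,13.73,16.14,0.25,12.302
3,35,85,17.5,13.11,13.11,15.00,0.21,10.248
4,40,85,17.5,12.04,12.04,14.04,0.22,10.192
5,35,80,15.0,12.81,12.81,14.62,0.21,9.860
6,40,80,15.0,11.84,11.84,13.77,0.22,9.915
7,35,80,20.0,15.24,15.24,17.43,0.24,12.589
8,40,80,20.0,13.84,13.84,16.23,0.25,12.358
9,37.5,75,15.0,13.24,13.24,15.31,0.23,11.012
10,37.5,85,15.0,11.63,11.63,13.35,0.20,9.063
11,37.5,75,20.0,15.62,15.63,18.14,0.26,13.832
12,37.5,85,20.0,13.72,13.73,15.82,0.23,11.515
13,37.5,80,17.5,13.38,13.42,15.53,0.23,11.257
14,37.5,80,17.5,13.39,13.40,15.52,0.23,11.242
15,37.5,80,17.5,13.50,13.51,15.59,0.23,11.298
16,37.5,80,17.5,13.50,13.50,15.58,0.23,11.289
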