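item_id,calibration,var_a,var_b,var_c,cov_ab,cov_ac,cov_bc
1,1,0.023,0.001,0.002,0.001,0.006,0.001
1,2,0.019,0.004,0.012,0.002,0.012,0.005
2,1,0.02,0.001,0.001,0.001,0.003,0.001
2,2,0.017,0.002,0.003,0.0,0.006,0.001
3,1,0.015,0.001,0.0,0.001,0.002,0.0
3,2,0.015,0.001,0.001,0.0,0.003,0.001
4,1,0.015,0.001,0.0,0.002,0.001,0.0
4,2,0.009,0.001,0.001,0.001,0.002,0.001
5,1,0.018,0.001,0.0,0.004,0.001,0.0
5,2,0.01,0.001,0.0,0.002,0.002,0.001
6,1,0.017,0.001,0.0,0.004,0.001,0.0
6,2,0.011,0.001,0.0,0.001,0.001,0.0
7,1,0.015,0.002,0.0,0.004,0.001,0.0
7,2,0.009,0.001,0.0,0.002,0.001,0.001
8,1,0.016,0.003,0.0,0.006,0.001,0.0
8,2,0.014,0.002,0.0,0.004,0.001,0.0
9,1,0.044,0.006,0.0,0.016,0.001,0.0
9,2,0.02,0.003,0.0,0.007,0.001,0.0
10,1,0.033,0.009,0.0,0.016,0.001,0.0
10,2,0.022,0.006,0.0,0.011,0.001,0.001
11,1,0.008,0.036,0.006,0.015,0.006,0.014
11,2,0.009,0.215,0.031,0.039,0.015,0.081
12,1,0.007,0.053,0.007,0.018,0.006,0.019
12,2,0.009,0.292,0.036,0.047,0.017,0.103
13,1,0.007,0.055,0.008,0.017,0.007,0.021
13,2,0.008,0.18,0.021,0.034,0.012,0.061
14,1,0.006,0.048,0.005,0.016,0.005,0.016
14,2,0.007,0.125,0.015,0.027,0.009,0.043
15,1,0.008,0.032,0.002,0.014,0.003,0.008
15,2,0.007,0.073,0.007,0.02,0.006,0.022
16,1,0.007,0.036,0.002,0.014,0.004,0.009
16,2,0.007,0.109,0.009,0.026,0.008,0.031
17,1,0.007,0.027,0.001,0.013,0.003,0.006
17,2,0.007,0.152,0.011,0.031,0.008,0.04
18,1,0.008,0.036,0.001,0.016,0.003,0.006
18,2,0.008,0.066,0.004,0.021,0.005,0.015
19,1,0.009,0.035,0.001,0.017,0.002,0.005
19,2,0.009,0.136,0.005,0.033,0.006,0.025
20,1,0.01,0.062,0.001,0.023,0.003,0.008
20,2,0.01,0.139,0.004,0.034,0.006,0.023
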