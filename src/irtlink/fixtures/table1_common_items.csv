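item_id,a_gen,b_gen,c_gen,a_cal1,b_cal1,c_cal1,a_cal2,b_cal2,c_cal2
1,1.5,-2.0,0.25,2.612,-0.843,0.213,2.162,-1.725,0.191
2,1.5,-1.5,0.25,2.707,-0.558,0.234,2.334,-1.333,0.212
3,1.5,-1.0,0.25,2.612,-0.297,0.232,2.358,-0.959,0.29
4,1.5,-0.5,0.25,2.751,-0.008,0.241,2.125,-0.728,0.228
5,1.5,0.0,0.25,2.83,0.283,0.258,2.14,-0.364,0.238
6,1.5,0.0,0.25,2.722,0.296,0.264,2.283,-0.338,0.248
7,1.5,0.5,0.25,2.596,0.536,0.241,2.013,-0.046,0.233
8,1.5,1.0,0.25,2.506,0.773,0.231,2.183,0.33,0.253
9,1.5,1.5,0.25,3.15,1.09,0.249,2.478,0.663,0.257
10,1.5,2.0,0.25,2.605,1.331,0.246,2.176,1.004,0.249
11,0.5,-2.0,0.25,1.022,-0.652,0.295,0.745,-1.518,0.284
12,0.5,-1.5,0.25,0.897,-0.523,0.245,0.685,-1.486,0.256
13,0.5,-1.0,0.25,0.86,-0.51,0.171,0.698,-1.071,0.234
14,0.5,-0.5,0.25,0.854,-0.209,0.181,0.715,-0.857,0.187
15,0.5,0.0,0.25,0.938,0.311,0.246,0.77,-0.447,0.225
16,0.5,0.0,0.25,0.904,0.205,0.233,0.715,-0.455,0.228
17,0.5,0.5,0.25,0.971,0.497,0.244,0.647,-0.276,0.173
18,0.5,1.0,0.25,0.924,0.841,0.248,0.762,0.248,0.227
19,0.5,1.5,0.25,0.946,1.087,0.245,0.655,0.562,0.229
20,0.5,2.0,0.25,0.826,1.352,0.225,0.647,0.86,0.216
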