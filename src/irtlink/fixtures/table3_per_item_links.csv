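item_id,u,se_u,v,se_v
1,1.208,0.105,-0.707,0.104
2,1.16,0.088,-0.686,0.069
3,1.108,0.077,-0.63,0.045
4,1.295,0.082,-0.718,0.047
5,1.322,0.088,-0.738,0.074
6,1.192,0.079,-0.691,0.069
7,1.29,0.086,-0.737,0.106
8,1.148,0.084,-0.557,0.134
9,1.271,0.111,-0.723,0.228
10,1.197,0.117,-0.589,0.287
11,1.372,0.21,-0.624,0.413
12,1.309,0.218,-0.801,0.516
13,1.232,0.194,-0.443,0.425
14,1.194,0.178,-0.607,0.406
15,1.218,0.171,-0.826,0.396
16,1.264,0.191,-0.714,0.444
17,1.501,0.238,-1.022,0.573
18,1.213,0.184,-0.772,0.49
19,1.444,0.256,-1.008,0.724
20,1.277,0.247,-0.866,0.811
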