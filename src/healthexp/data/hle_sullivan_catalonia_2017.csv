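age,female_hle,female_se,male_hle,male_se
0,66.08,0.6539,66.62,0.5869
1,65.23,0.6554,65.78,0.5883
5,61.5,0.6496,62.12,0.5805
10,56.8,0.6443,57.26,0.5781
15,51.86,0.6429,52.51,0.5711
20,47.24,0.6317,47.68,0.5681
25,42.35,0.6292,42.96,0.5607
30,37.57,0.6239,38.35,0.5519
35,33.18,0.6113,33.64,0.5476
40,28.96,0.5973,29.32,0.5358
45,24.87,0.5839,24.95,0.5285
50,20.82,0.5681,20.72,0.5184
55,17.1,0.551,17.28,0.4984
60,14.01,0.5271,14.17,0.4797
65,10.68,0.5027,11.43,0.4579
70,7.81,0.4716,8.96,0.4306
75,5.78,0.4178,6.73,0.3963
80,4.05,0.3794,4.15,0.3603
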