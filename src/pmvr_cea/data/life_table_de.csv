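age,q_male,q_female
50,0.003940,0.002160
51,0.004287,0.002326
52,0.004665,0.002505
53,0.005076,0.002698
54,0.005523,0.002906
55,0.006010,0.003130
56,0.006564,0.003386
57,0.007169,0.003664
58,0.007830,0.003964
59,0.008552,0.004289
60,0.009340,0.004640
61,0.010202,0.005065
62,0.011143,0.005528
63,0.012171,0.006035
64,0.013294,0.006587
65,0.014520,0.007190
66,0.015908,0.007917
67,0.017429,0.008718
68,0.019095,0.009600
69,0.020920,0.010571
70,0.022920,0.011640
71,0.025328,0.013030
72,0.027989,0.014586
73,0.030930,0.016328
74,0.034179,0.018277
75,0.037770,0.020460
76,0.042020,0.023281
77,0.046748,0.026491
78,0.052008,0.030144
79,0.057860,0.034300
80,0.064370,0.039030
81,0.071874,0.044743
82,0.080253,0.051291
83,0.089609,0.058798
84,0.100056,0.067404
85,0.111720,0.077270
86,0.124009,0.087611
87,0.137649,0.099335
88,0.152789,0.112628
89,0.169595,0.127701
90,0.188250,0.144790
91,0.204912,0.160488
92,0.223048,0.177889
93,0.242790,0.197176
94,0.264279,0.218554
95,0.287670,0.242250
96,0.307730,0.262223
97,0.329189,0.283844
98,0.352145,0.307247
99,0.376701,0.332579
100,0.402970,0.360000
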