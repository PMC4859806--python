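point	Dorsal	Twist	Snail
1	0.85326	0.93224	0.985
2	0.77516	0.88219	0.976
3	0.68914	0.81279	0.967
4	0.59981	0.70658	0.957
5	0.51152	0.54216	0.902
6	0.42792	0.34085	0.441
7	0.35175	0.17674	0.043
8	0.28472	0.08318	0.005
9	0.22757	0.03873	0.001
10	0.18021	0.01842	0
11	0.14193	0.00892	0
12	0.11165	0.00433	0
13	0.08811	0.00208	0
14	0.07001	0.00097	0
15	0.05618	0.00044	0
16	0.0456	0.00019	0
17	0.03746	0.00008	0
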