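7
9
24
45
59
62
63
66
67
69
70
73
74
76
77
80
81
84
95
97
99
114
116
118
143
147
150
152
156
158
159
163
167
171
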