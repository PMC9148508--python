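42
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.050000 0.316667 0.050000 0.583333
0.050000 0.316667 0.050000 0.583333
0.850000 0.050000 0.050000 0.050000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
43
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.050000 0.316667 0.050000 0.583333
0.050000 0.316667 0.050000 0.583333
0.850000 0.050000 0.050000 0.050000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
44
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.050000 0.316667 0.050000 0.583333
0.050000 0.316667 0.050000 0.583333
0.850000 0.050000 0.050000 0.050000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
45
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.050000 0.316667 0.050000 0.583333
0.050000 0.316667 0.050000 0.583333
0.850000 0.050000 0.050000 0.050000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
46
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.050000 0.316667 0.050000 0.583333
0.050000 0.316667 0.050000 0.583333
0.850000 0.050000 0.050000 0.050000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
47
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.050000 0.316667 0.050000 0.583333
0.050000 0.316667 0.050000 0.583333
0.850000 0.050000 0.050000 0.050000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
48
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.050000 0.316667 0.050000 0.583333
0.050000 0.316667 0.050000 0.583333
0.850000 0.050000 0.050000 0.050000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
49
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.050000 0.316667 0.050000 0.583333
0.050000 0.316667 0.050000 0.583333
0.850000 0.050000 0.050000 0.050000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
50
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.050000 0.316667 0.050000 0.583333
0.050000 0.316667 0.050000 0.583333
0.850000 0.050000 0.050000 0.050000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
51
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.050000 0.316667 0.050000 0.583333
0.050000 0.316667 0.050000 0.583333
0.850000 0.050000 0.050000 0.050000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
52
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.050000 0.316667 0.050000 0.583333
0.050000 0.316667 0.050000 0.583333
0.850000 0.050000 0.050000 0.050000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
53
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.050000 0.316667 0.050000 0.583333
0.050000 0.316667 0.050000 0.583333
0.850000 0.050000 0.050000 0.050000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
54
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.050000 0.316667 0.050000 0.583333
0.050000 0.316667 0.050000 0.583333
0.850000 0.050000 0.050000 0.050000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
55
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.050000 0.316667 0.050000 0.583333
0.050000 0.316667 0.050000 0.583333
0.850000 0.050000 0.050000 0.050000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
56
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.050000 0.316667 0.050000 0.583333
0.050000 0.316667 0.050000 0.583333
0.850000 0.050000 0.050000 0.050000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
57
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.050000 0.316667 0.050000 0.583333
0.050000 0.316667 0.050000 0.583333
0.850000 0.050000 0.050000 0.050000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
58
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.050000 0.316667 0.050000 0.583333
0.050000 0.316667 0.050000 0.583333
0.850000 0.050000 0.050000 0.050000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
0.250000 0.250000 0.250000 0.250000
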