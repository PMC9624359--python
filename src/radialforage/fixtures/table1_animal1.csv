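label,x1,x2
1,5.144,5.1
2,3.599,5.875
3,-3.827,-3.001
4,0.523,1.476
5,-2.426,1.196
6,2.964,3.077
7,1.206,-0.038
8,0.81,1.658
9,2.517,-3.601
10,-6.446,-3.706
11,2.64,-0.369
12,11.79,-1.516
13,6.28,1.79
14,2.901,2.826
15,-2.97,-5.068
16,1.808,-1.38
17,2.88,1.492
18,0.831,-2.256
19,-6.048,-3.446
20,-1.168,-0.798
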