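label,x1,x2
1,2.497,3.872
2,-5.704,1.842
3,-2.49,3.208
4,-0.116,-0.715
5,-5.141,-2.414
6,2.448,0.911
7,-3.359,4.763
8,-3.88,0.099
9,-7.157,-1.276
10,2.141,0.392
11,3.361,2.267
12,2.28,-2.018
13,1.01,4.84
14,-6.651,-1.185
15,2.314,-1.31
16,2.03,3.666
17,3.005,-1.613
18,1.953,1.34
19,0.97,4.742
20,-7.194,-4.894
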