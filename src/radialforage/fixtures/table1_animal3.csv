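label,x1,x2
1,-3.991,-2.857
2,-3.353,1.956
3,-3.834,-2.211
4,-8.3,-4.745
5,-1.608,0.831
6,1.692,-1.398
7,3.451,0.995
8,0.298,4.509
9,-1.484,3.148
10,12.134,-1.437
11,1.058,-2.188
12,-6.652,-0.437
13,-4.29,-0.811
14,-0.353,0.198
15,2.642,0.31
16,-0.634,0.266
17,6.764,1.434
18,3.349,-1.626
19,2.779,3.59
20,-0.69,-4.584
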