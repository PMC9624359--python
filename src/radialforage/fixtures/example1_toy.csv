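label,x1,x2
1,1,2
2,-2,4
3,0,5
4,3,1
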