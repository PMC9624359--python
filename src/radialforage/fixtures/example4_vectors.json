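{"v": [1, 4, 9, 10], "w": [2, 3, 7, 9, 12, 14, 17]}
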