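z,let_u
1,30.5
2,103.4
6,208
10,233
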