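condition,low_sa,high_sa
LL,102,310
LH,151,271
HL,153,277
HH,207,234
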