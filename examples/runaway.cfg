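# Strong signal honesty (GSB = 0.8): signal and body size run away.
GSS = 1.0
GBB = 1.0
GAA = 1.0
GSB = 0.8
bA = 0.2
cA = 0.05
cB = 0.2
cS = 0.05
deltaAS = 0.4
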