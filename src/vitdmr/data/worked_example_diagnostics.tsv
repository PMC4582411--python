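name	value
f_stat	219.7
r2	0.005
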