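nod	12.400	13.600	nod bout
nod	45.000	45.300	single
sleep	100.000	160.000	asleep
nod	200.250	201.000	nod
posture	5.000	8.000	lean
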