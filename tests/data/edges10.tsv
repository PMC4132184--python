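# 10-row fixture: 8 unique edges after dropping one self-loop and one duplicate pair
A	B	known
B	C	predicted
C	D
D	E	known
E	A	predicted
B	D	known
C	C	known
A	B	predicted
F	G	predicted
G	H	known
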