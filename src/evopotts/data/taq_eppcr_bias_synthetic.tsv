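base	A	C	G	T
A	0	5	22	17
C	5	0	2	11
G	11	2	0	5
T	17	22	5	0
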