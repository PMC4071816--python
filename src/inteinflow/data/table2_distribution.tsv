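allele	tree_topology	halobacteria	bacteria	other_euryarchaeota
cdc21-a	Monophyletic	55	4	16
cdc21-c	Monophyletic	1	0	0
dtd	Monophyletic	6	0	0
gyrB	Monophyletic	6	19	1
helicase-b	Monophyletic	1	2	1
ligase	Monophyletic	1	0	0
pol-IIb	Monophyletic	9	0	1
polB-d	Monophyletic	6	0	1
rfc-a	Monophyletic	16	0	13
rfc-d	Monophyletic	5	0	0
rir1-b	Monophyletic	15	55	5
rir1-g	Monophyletic	4	15	0
rir1-k	Monophyletic	5	1	0
rir1-l	Monophyletic	3	3	0
rpolA	Monophyletic	10	0	0
top6B	Monophyletic	8	0	0
topA	Monophyletic	4	0	1
udp	Monophyletic	7	2	6
rir1-m	Monophyletic	1	4	0
polB-c	Monophyletic	20	1	1
polB-a	Polyphyletic-bacteria	16	2	1
polB-b	Polyphyletic-bacteria	38	3	0
pol-IIa	Polyphyletic-Euryarchaeota	75	0	16
cdc21-b	Polyphyletic-Euryarchaeota	51	1	3
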