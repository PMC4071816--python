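allele	host_gene	extein_annotation	new_allele	new_host_gene
cdc21-a	cdc21	Cell division control protein 21	0	0
cdc21-b	cdc21	Cell division control protein 21	0	0
cdc21-c	cdc21	Cell division control protein 21	0	0
polB-d	polB	DNA polymerase B1	0	0
polB-a	polB	DNA polymerase B1	0	0
polB-b	polB	DNA polymerase B1	0	0
polB-c	polB	DNA polymerase B1	0	0
pol-IIa	pol-II	DNA polymerase II large subunit	0	0
pol-IIb	pol-II	DNA polymerase II large subunit	1	0
dtd	dtd	Deoxycytadine triphosphate deaminase	1	1
gyrB	gyrB	DNA gyrase subunit B	0	0
helicase-b	helicase	ATP-dependent helicase	1	0
ligase	ligase	ATP-dependent DNA ligase I	1	1
rfc-a	rfc	Replication factor C small subunit	0	0
rfc-d	rfc	Replication factor C small subunit	1	0
rir1-l	rir1	Ribonucleoside-diphosphate reductase	1	0
rir1-k	rir1	Ribonucleoside-diphosphate reductase	0	0
rir1-b	rir1	Ribonucleoside-diphosphate reductase	0	0
rir1-g	rir1	Ribonucleoside-diphosphate reductase	0	0
rir1-m	rir1	Ribonucleoside-diphosphate reductase	1	0
rpolA	rpolA	DNA-directed RNA polymerase subunit A	0	0
udp	udp	UDP-glucose 6-dehydrogenase	0	0
topA	topA	DNA topoisomerase I	0	0
top6B	top6B	DNA topoisomerase VI subunit B	0	0
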