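position	location	region	type	GZST	JXLS	GZLP	HNSN
matK	exon	LSC	T/C	T	T	C	C
matK	exon	LSC	T/C	T	T	C	C
matK-trnK	spacer	LSC	A/G	A	A	G	A
trnK-rps16	spacer	LSC	T/G	T	T	G	T
trnK-rps16	spacer	LSC	T/C	C	C	C	T
trnK-rps16	spacer	LSC	A/C	A	A	C	C
rps16-trnQ	spacer	LSC	T/G	T	T	G	G
trnQ-psbK	spacer	LSC	T/G	G	G	T	G
psbK-psbI	spacer	LSC	T/C	T	T	C	T
trnG	intron	LSC	A/G	G	G	G	A
trnR-atpA	spacer	LSC	T/C	T	T	T	C
atpF	intron	LSC	A/G	G	G	G	A
atpF-atpH	spacer	LSC	T/C	C	C	C	T
atpH-atpI	spacer	LSC	A/C	C	C	A	A
atpH-atpI	spacer	LSC	C/G	G	G	G	C
rps2-rpoC2	spacer	LSC	A/T	A	A	A	T
rpoC2	exon	LSC	T/G	T	T	G	T
rpoC1	exon	LSC	A/G	A	A	G	G
rpoB-trnC	spacer	LSC	T/G	G	G	T	G
trnT-psbD	spacer	LSC	T/G	G	G	G	T
ndhC-trnV	spacer	LSC	A/C	C	C	C	A
trnV	intron	LSC	A/T	T	T	A	A
atpB	exon	LSC	T/C	T	T	C	C
accD-psaI	spacer	LSC	T/G	G	G	T	G
psaI-ycf4	spacer	LSC	A/G	G	G	A	A
ycf4-cemA	spacer	LSC	T/G	G	G	T	G
psbE-petL	spacer	LSC	A/G	A	A	A	G
psbE-petL	spacer	LSC	A/G	G	G	G	A
psbE-petL	spacer	LSC	A/C	C	C	C	A
rpl20-rps12	spacer	LSC	A/C	A	A	C	A
psbB	exon	LSC	A/C	A	A	C	C
rps11-rpl36	spacer	LSC	A/C	A	A	C	C
rpl14	exon	LSC	A/T	A	A	T	T
ndhF	exon	SSC	A/C	A	A	C	C
ndhF	exon	SSC	T/C	C	C	T	C
ndhF-rpl32	spacer	SSC	A/C	C	C	C	A
ndhF-rpl32	spacer	SSC	A/C	A	A	C	C
rpl32	exon	SSC	T/G	G	G	G	T
psaC-ndhE	spacer	SSC	A/C	A	A	C	A
ndhA	exon	SSC	A/G	G	G	A	G
ndhH	exon	SSC	T/G	T	T	G	G
ycf1	exon	SSC	T/C	T	T	C	C
ycf1	exon	SSC	T/C	C	C	T	C
ycf1	exon	SSC	A/G	A	A	G	G
ycf1	exon	SSC	A/G	A	A	A	G
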