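position	location	region	length	GZST	JXLS	GZLP	HNSN
matK-trnK	spacer	LSC	9	Insertion	Insertion	Deletion	Insertion
trnK-rps16	spacer	LSC	15	Deletion	Deletion	Insertion	Insertion
rps16-trnQ	spacer	LSC	2	Deletion	Insertion	Insertion	Insertion
rps16-trnQ	spacer	LSC	24	Insertion	Insertion	Insertion	Deletion
trnG-trnR	spacer	LSC	9	Insertion	Insertion	Insertion	Deletion
petN-psbM	spacer	LSC	153	Insertion	Insertion	Insertion	Deletion
trnE-trnT	spacer	LSC	5	Deletion	Deletion	Insertion	Deletion
trnfM-rps14	spacer	LSC	30	Insertion	Insertion	Deletion	Deletion
ndhC-trnV	spacer	LSC	126	Insertion	Insertion	Insertion	Deletion
ndhC-trnV	spacer	LSC	458	Deletion	Deletion	Insertion	Insertion
clpP	intron	LSC	3	Insertion	Insertion	Insertion	Deletion
petD-rps11	spacer	LSC	15	Deletion	Deletion	Insertion	Deletion
rpl16	intron	LSC	8	Deletion	Deletion	Insertion	Insertion
trnN-ycf1	spacer	IR	9	Insertion	Insertion	Deletion	Insertion
ccsA-ycf1	spacer	SSC	22	Deletion	Deletion	Deletion	Insertion
ndhE-ndhG	spacer	SSC	6	Deletion	Deletion	Deletion	Insertion
ycf1-trnN	spacer	IR	9	Insertion	Insertion	Deletion	Insertion
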