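position	region	inv_length	flank_length	GZST	JXLS	GZLP	HNSN
trnH-psbA	LSC	8	21	No	No	Yes	No
petA-psbJ	LSC	10	17	No	No	Yes	No
petA-psbJ	LSC	12	29	No	No	Yes	No
rpl32-trnL	SSC	3	22	No	No	Yes	Yes
ccsA-ycf1	SSC	23	17	No	No	Yes	Yes
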