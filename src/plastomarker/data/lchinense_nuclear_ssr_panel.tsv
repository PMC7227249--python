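locus	forward_primer	reverse_primer	predicted_size	motif	repeats	A	Ho	He	H
Loci01	CGATAGCGAGAAGAGATACGGG	AGAGAAAAATCAGGCCAGTCCA	248	CA	7	16	0.3564	0.8693	2.2622
Loci02	CGGGGTCTTGATTTTGGAGAGA	CTGTAGACGTGCTCTTCCGATT	269	AG	10	8	0.3084	0.4916	1.0601
Loci03	GTTTTCTCCAATGCTCCACACC	CTCTATAGTCCTCGTGTCGCAC	253	AG	13	24	0.2909	0.9344	2.9145
Loci04	CGTTTCAAATAGGTGGGAGGGA	TGCTGTCCCAAAGCTTCACTAA	256	CT	7	21	0.7532	0.913	2.6479
Loci05	AGAGGAAGTGGAGGAAGAAGGA	TGCCCTCATTTATCTCTCTCGC	168	AG	13	12	0.1101	0.1919	0.5557
Loci06	TCGAGTTGGCGAGTAATTGTCA	TCTTTGTCGCTTTCTCTCCCTC	250	AG	14	21	0.573	0.9156	2.6439
Loci07	ATGTCCAGTCGTAGAAGGGAGA	ATCTTACAAATTCCCCCTGGGC	280	TC	13	27	0.7733	0.9023	2.7063
Loci08	CCAAGACGAGAACGATCGATCT	AAGTGAGAAAATGCACGTGGTG	157	TC	7	19	0.7113	0.8737	2.4331
Loci09	AGGGGATTACTGACGTCGAGTA	GAGTATCATAGGCCCATTACCCT	260	AG	13	28	0.3486	0.9198	2.8313
Loci10	GGATTTAGTTCGGGGAAGACGT	TAGGGCCGTTTGCAACATTTTT	236	CT	7	22	0.1972	0.9059	2.606
Loci11	CATGCCAGGCCTGTTAAAAGTC	GCTAGCTCTGACAGGCTTCTAG	179	GT	7	25	0.7944	0.9034	2.5901
Loci12	GGCACAGATCAAAAATCGCACT	CTTCCATGCCTCTCCGCCATTA	140	GA	18	24	0.7156	0.7804	1.9415
Loci13	CAACCTTCTCTGTCACCTCCGA	TAAGTAGTGGAGAGCATGCGG	145	TC	14	26	0.486	0.9221	2.8333
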