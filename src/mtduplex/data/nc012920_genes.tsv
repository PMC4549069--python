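# Human mitochondrial gene coordinates (NC_012920 / rCRS convention).
# 1-based inclusive, L-strand coordinates; coding_strand H = reverse complement.
# 37 genes (13 protein, 22 tRNA, 2 rRNA) plus the two control-region segments
# annotated as noncoding.
gene	category	start	end	coding_strand	frame_offset
MT-CR2	noncoding	1	576	L	0
MT-TF	tRNA	577	647	L	0
MT-RNR1	rRNA	648	1601	L	0
MT-TV	tRNA	1602	1670	L	0
MT-RNR2	rRNA	1671	3229	L	0
MT-TL1	tRNA	3230	3304	L	0
MT-ND1	protein	3307	4262	L	0
MT-TI	tRNA	4263	4331	L	0
MT-TQ	tRNA	4329	4400	H	0
MT-TM	tRNA	4402	4469	L	0
MT-ND2	protein	4470	5511	L	0
MT-TW	tRNA	5512	5579	L	0
MT-TA	tRNA	5587	5655	H	0
MT-TN	tRNA	5657	5729	H	0
MT-TC	tRNA	5761	5826	H	0
MT-TY	tRNA	5826	5891	H	0
MT-CO1	protein	5904	7445	L	0
MT-TS1	tRNA	7446	7514	H	0
MT-TD	tRNA	7518	7585	L	0
MT-CO2	protein	7586	8269	L	0
MT-TK	tRNA	8295	8364	L	0
MT-ATP8	protein	8366	8572	L	0
MT-ATP6	protein	8527	9207	L	0
MT-CO3	protein	9207	9990	L	0
MT-TG	tRNA	9991	10058	L	0
MT-ND3	protein	10059	10404	L	0
MT-TR	tRNA	10405	10469	L	0
MT-ND4L	protein	10470	10766	L	0
MT-ND4	protein	10760	12137	L	0
MT-TH	tRNA	12138	12206	L	0
MT-TS2	tRNA	12207	12265	L	0
MT-TL2	tRNA	12266	12336	L	0
MT-ND5	protein	12337	14148	L	0
MT-ND6	protein	14149	14673	H	0
MT-TE	tRNA	14674	14742	H	0
MT-CYB	protein	14747	15887	L	0
MT-TT	tRNA	15888	15953	L	0
MT-TP	tRNA	15956	16023	H	0
MT-CR1	noncoding	16024	16569	L	0
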