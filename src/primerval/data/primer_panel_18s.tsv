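name	forward	reverse	min_len	max_len
1391f-EukBr	GTACACACCGCCCGTC	TGATCCTTCTGCAGGTTCACCTAC	50	250
1813F-2646R	CTGCGTGAGAGGTGAAAT	GCTACCTTGTTACGACTTTT	500	1000
18SILVOmidF-18SILVOmidR	CAAGTCTGGTGCCAGCAG	GAGTCTCGCTCGTTATCGG	500	1000
3NDf-1132rmod	GGCAAGTCTGGTGCCAG	TCCGTCAATTYCTTTAAGT	300	700
EcoF-EcoR	GGTTAAAAMGYTCGTAGTTG	TGGTGGTGCCCTTCCGTCA	300	700
Ek-NSF573-Ek-NSR951	CGCGGTAATTCCAGCTCCA	TTGGYRAATGCTTTCGC	200	500
Euka02	TTTGTCTGSTTRATTSCG	CACAGACCTGTTATTGC	30	400
F_1183-R_1631	AATTTGACTCAACACGGG	TACAAAGGGCAGGGACG	300	600
FO4-R22	GCTTGTCTCAAAGATTAAGCC	GCCTGCTGCCTTCCTTGGA	200	500
MMSF-MMSR	GGTGCCAGCAGCCGCGGTA	CTTTAAGTTTCAGCTTTGC	300	700
Nema02	AAGTCTGGTGCCAGCAGC	GTTTACGGTYAGAACTAGGG	325	801
NemF-18Sr2b	GGGGAAGTATGGTTGCAAA	TACAAAGGGCAGGGACGTAAT	300	700
NemFopt-18Sr2bopt	GGGGWAGTATGGTTGCAAA	TGTGTACAAAKGRCAGGGAC	300	700
NF1-18Sr2b	GGTGGTGCATGGCCGTTCTTAGTT	TACAAAGGGCAGGGACGTAAT	200	500
SSU_F04-SSU_R22	GCTTGTCTCAAAGATTAAGCC	CCTGCTGCCTTCCTTGGA	200	500
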