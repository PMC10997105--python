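primer	coverage	mean_len	min_len_obs	max_len_obs	resolution_species	resolution_genus	resolution_family
1391f-EukBr	0.10	129.4	87	138	0.87	0.96	0.97
1813F-2646R	0.36	844.9	760	987	0.95	1.00	1.00
18SILVOmidF-18SILVOmidR	0.96	742.3	664	905	0.92	0.99	1.00
3NDf-1132rmod	0.97	562.3	484	697	0.91	0.99	1.00
EcoF-EcoR	0.98	508.3	430	671	0.91	0.99	1.00
Ek-NSF573-Ek-NSR951	0.96	343.6	274	446	0.89	0.98	0.99
Euka02	0.97	99.2	50	330	0.78	0.95	0.99
F_1183-R_1631	0.92	414.4	331	565	0.86	0.98	0.99
FO4-R22	0.14	375.5	281	413	0.95	1.00	1.00
MMSF-MMSR	0.97	540.3	462	675	0.91	0.99	1.00
Nema02	0.94	435.6	357	599	0.90	0.98	1.00
NemF-18Sr2b	0.91	484.4	401	635	0.87	0.98	0.99
NemFopt-18Sr2bopt	0.91	489.4	406	640	0.87	0.98	0.99
NF1-18Sr2b	0.91	320.4	237	471	0.85	0.98	0.99
SSU_F04-SSU_R22	0.14	375.5	281	413	0.95	1.00	1.00
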