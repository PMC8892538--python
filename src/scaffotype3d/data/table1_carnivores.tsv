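ref_chrom	puma	cheetah	leopard	tiger	clouded_leopard	dingo (2n=78)	african_wild_dog (2n=78)	red_fox (2n=34)	black_bear (2n=74)	grizzly_bear (2n=74)	polar_bear (2n=74)
A1	9	1	12	13	1	28c+30 + 31b+38b+10a +8c+39c+1a+21b	30a+1 + 34b+32b+2b +29c+11c+37b+19b	3b+15b+7b+14b+9e +11b+12c+17c	36b+27 + 12	36b+35 + 10	11a+6 + 16
A2	15	4	5	14	4	7 + 14b+15a+31a	26 + 8a+28b+34a	3a+7a+8a	28a+2	14a+5	14a+4
A3	14	9	6	12	9	16 + 36a+3a+32a	23 + 24b+33b+5b	11a+1b+10d+5a	33 + 15	15 + 16	23 + 7
B1	5	3	4	6	3	22a+14a+28b+13a+29a +33 + 35a+39a	13a+8b+30b+36d +7a+6 + 3a+11a	10a+7c+3c+6f+12a+9c+11d	35 + 31+32	26 + 1+8	28 + 12+9
B2	18	6	1	10	6	26b+11 + 2b	15a+35 + 38b	14c+2a	11 + 9+14	22 + 30+4	32 + 30+15
B3	4	7	11	5	7	39b+5 + 13c+38a	11b+17 + 36b+32a	11c+16b+6d+15a	6 + 7+8 + 49+10	20 + 29+16 + 6206+25	29 + 36+38 + 37+25
B4	6	8	3	11	8	8d+12 + 3b+13b	29d+18 + 33a+36c	9d+5c+10c+6e	34 + 19+18	31 + 27+24	31 + 27+22
C1	16	2	7	7	2	9b+8a+13d+4a+32b +29b+23 + 22b+28a	31c+29a+36a+25a+5a +7b+14 + 13b+30c	14g+9g+6c+17a+5b +8e+10b+3d	17 + 26+36a+13	18 + 9+36a+2	33 + 13+11b+2
C2	17	5	2	4	5	27 + 24+36b+21a	20 + 16+24a+19a	16a+2b+1c+17d	25 + 29	3 + 33	5 + 21
D1	12	11	8	8	11	9d+20 + 15b	31a+9 + 28a	14e+1a+8c	5 + 16	32 + 21	17 + 24
D2	19	14	9	9	14	17a+1b+18	22b+37a+21	6b+12b+16c	37	12	8
D3	8	13	10	19	13	17b+2a+34a	22a+38c+4a	6a+8d+4b	4 + 30	17 + 34	34 + 19
D4	13	12	15	3	12	2c+10b+6b	38a+2a+27a	2c+14a+9b	22 + 24	28 + 23	35 + 18
E1	1	18	16	17	18	9c+6a	31b+27b	14f+9a	28b+20	14b+19	14b+26
E2	7	17	18	16	17	2d+8b+9a	29b+31d	2d+9f+14h	23	13	20
E3	2	19	17	15	19	4b	25b	17b	3a	11b	3a
F1	3	16	13	18	16	34b+19	4b+12	4c+8b	3b	11a	3b
F2	11	15	14	2	15	26a+25 + 35b	15b+10 + 3b	14d+4a	21	7	10
X	10	10	19	1	10	37	39	13	1	37	1
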