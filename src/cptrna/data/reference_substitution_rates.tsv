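# Published transition (ts) and transversion (tv) pattern-table entries per
# tRNA isotype for gymnosperm chloroplast tRNAs (x100 scale; each 4x4 row
# holds one ts cell and two tv cells, so ts + 2*tv = 25).
isotype	ts	tv
Alanine	12.53	6.23
Asparagine	19.36	2.82
Cysteine	20.12	2.44
Glutamate	21.13	1.94
Histidine	11.40	6.80
Leucine	15.56	4.72
Methionine	13.35	5.83
Proline	20.69	2.16
Threonine	17.68	3.66
Tyrosine	16.91	4.04
Arginine	20.05	2.48
Aspartate	25.00	0.00
Glutamine	16.02	4.49
Glycine	12.61	6.19
Isoleucine	14.85	5.08
Lysine	14.25	5.37
Phenylalanine	22.41	1.29
Serine	16.56	4.22
Tryptophan	21.50	1.75
Valine	14.52	5.24
Overall	18.63	3.19
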