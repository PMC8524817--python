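# Published per-tRNA folding free energies (kcal/mol) for gymnosperm
# chloroplast tRNA structural variants, transcribed verbatim from the
# literature survey this package's analyses parallel (including its
# repeated rows). Species abbreviations as printed.
structural_type	species	isotype	anticodon	delta_g
Type1	S. eriopus	Thr	GGU	-16.0
Type1	T. baccata	Met	CAU	-12.1
Type1	C. lanceolata	Gly	UCC	-9.6
Type1	N. longibracteata	Asn	GUU	-12.8
Type2	T. fargesii	Gly	UCC	-19.5
Type2	S. sempervirens	Gly	GCC	-28.3
Type2	C. nootkatensis	Pro	GGG	-18.3
Type2	C. nootkatensis	Ile	CAU	-18.0
Type2	C. oliveri	Met	CAU	-11.8
Type2	L. decidua	Thr	GGU	-16.3
Type2	P. armandii	Lys	UUU	-20.6
Type2	P. sinensis	Lys	UUU	-20.6
Type2	P. sinensis	Thr	GGU	-20.3
Type2	S. verticillata	Gln	UUG	-21.6
Type2	P. abies	Lys	UUU	-20.6
Type2	P. sinensis	Thr	GGU	-20.3
Type2	T. flousiana	Thr	GGU	-15.1
Type3	A. dammara	Ser	GCU	-36.8
Type3	A. dammara	Tyr	GUA	-40.9
Type3	A. dammara	Ser	UGA	-30.6
Type3	A. dammara	Ser	GGA	-30.6
Type3	A. dammara	Leu	UAA	-30.2
Type3	A. dammara	Leu	CAA	-26.7
Type3	A. koreana	Ser	GCU	-38.5
Type3	A. koreana	Ser	GCU	-38.5
Type3	A. koreana	Ser	UGA	-31.6
Type3	A. koreana	Leu	CAA	-26.4
Type3	A. koreana	Ser	GGA	-35.3
Type3	A. koreana	Tyr	GUA	-33.7
Type3	A. argotaenia	Ser	GCU	-35.6
Type3	A. argotaenia	Tyr	GUA	-33.6
Type3	A. argotaenia	Ser	UGA	-32.3
Type3	A. argotaenia	Ser	GGA	-32.2
Type3	A. argotaenia	Leu	UAA	-32.9
Type3	A. argotaenia	Leu	CAA	-26.5
Type3	A. heterophylla	Tyr	GUA	-38.8
Type3	A. heterophylla	Leu	CAA	-24.9
Type4	P. sinensis	Tyr	GUA	-32.1
Type4	P. sinensis	Ser	UGA	-21.8
Type4	T. chinensis	Ser	UGA	-32.5
Type4	G. biloba	Ser	UGA	-26.6
Normal	T. flousiana	Lys	UUU	-31.0
Normal	T. flousiana	Gln	UUG	-26.9
Normal	T. flousiana	Gly	GCC	-30.4
Normal	T. baccata	Lys	UUU	-28.1
Normal	N. longibracteata	Glu	UUC	-24.8
Normal	A. dammara	Gln	UUG	-25.8
Normal	A. dammara	Gly	UCC	-24.8
Normal	A. dammara	Cys	GCA	-27.7
Normal	A. koreana	Pro	UGG	-25.0
Normal	A. koreana	Ile	CAU	-23.5
Normal	A. koreana	Phe	GAA	-28.7
Normal	A. argotaenia	Gly	UCC	-24.8
Normal	A. argotaenia	Arg	UCU	-19.9
Normal	A. argotaenia	Val	UAC	-30.0
Normal	A. argotaenia	His	GUG	-26.4
Normal	A. heterophylla	Cys	GCA	-29.5
Normal	A. heterophylla	Trp	CCA	-23.0
Normal	C. deodara	Gly	GCC	-26.7
Normal	C. oliveri	Pro	UGG	-26.9
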