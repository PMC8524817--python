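# Published region-length counts over 1779 gymnosperm chloroplast tRNAs,
# transcribed verbatim (the source table's ANC-arm counts sum to 1799 and
# its variable-region counts to 1781; reproduced as printed).
region	length	count
ac_arm	0	3
ac_arm	1	3
ac_arm	2	1
ac_arm	3	21
ac_arm	4	18
ac_arm	5	12
ac_arm	6	58
ac_arm	7	1659
ac_arm	8	4
d_arm	1	2
d_arm	3	609
d_arm	4	1168
d_loop	6	1
d_loop	7	341
d_loop	8	281
d_loop	9	719
d_loop	10	162
d_loop	11	249
d_loop	12	25
d_loop	26	1
anc_arm	4	135
anc_arm	5	1664
anc_loop	7	1743
anc_loop	9	24
anc_loop	10	2
anc_loop	12	10
variable	1	3
variable	2	7
variable	3	97
variable	4	283
variable	5	1049
variable	6	225
variable	7	63
variable	8	1
variable	11	37
variable	15	1
variable	16	13
variable	17	1
variable	20	1
psi_arm	4	11
psi_arm	5	1767
psi_arm	6	1
psi_loop	7	1779
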