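# Curated mutagenesis records: published percentage changes (mutant vs wild type)
# in structural-entropy features for experimentally characterized riboswitch mutants.
# disrupts_one_structure = yes marks structural mutants (designed to disrupt exactly
# one of the two functional conformations). The ROSE-P2 deletion mutant is one
# nucleotide shorter than its 135-nt wild type and carries a length-adjusted
# decision threshold of -0.74 (entropy scales ~linearly with length).
wild_type_id	mutant_id	disrupts_one_structure	threshold	dRND	dBJK	dBJKbp	dSil
TPP_Bsub	plus30	yes	0	0.7	-2.6	-3.9	-55.2
TPP_Bsub	plus118	yes	0	-0.4	5.3	-0.7	-50.3
TPP_Bsub	plus80	no	0	0.8	3.3	0.8	-38.2
TPP_Bsub	plus97	no	0	-0.8	1.9	1.6	-63.2
FMN_Bsub	G34C/G35C	yes	0	-1.6	-5.5	-2.4	15.4
FMN_Bsub	C86T	no	0	0.2	-0.1	0.6	11.8
FMN_Bsub	C49T	no	0	0.3	0.5	0	-14.3
FMN_Bsub	G157A/G160A	yes	0	0	-0.7	-0.9	66.7
SAMI_Bsub	Ma	no	0	2.3	15.8	10.7	-48.8
SAMI_Bsub	Mab	yes	0	-2.3	-0.29	-0.4	4.1
SAMI_Bsub	Mc	yes	0	0.3	-0.31	-0.8	-0.3
SAMI_Bsub	Mabc	no	0	-1.1	-0.32	-0.7	-3.2
Magnesium_Sent	C145G	yes	0	1.7	-1.8	-4.7	-10.1
Magnesium_Sent	M1	yes	0	0.4	-3.8	-5.8	-43
Magnesium_Sent	M2	yes	0	-1.4	-1.9	-1.2	-5.7
Magnesium_Bsub	M5	yes	0	2.7	0.9	0.7	-12.3
Magnesium_Bsub	M6	yes	0	3.9	12.4	8	-14.8
ROSEP2_Brady	dG83	yes	-0.74	-2.6	-8.1	-4.7	8.6
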