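# Published Target-AID CRISPR-STOP guide designs against the PERV gag/pol/env genes.
# target_with_pam is the 23-mer protospacer+PAM in guide orientation; editing_window is
# the printed window (protospacer positions 2-5, i.e. 16-19 bp upstream of the PAM);
# position is the printed CDS coordinate; perv_a/b/c are the printed o/x presence calls.
# stop_route group labels are filled down over grouped rows.
gene	direction	stop_route	target_with_pam	editing_window	position	perv_a	perv_b	perv_c
gag	+	CAA	CCAACGCCTCACGGGGTTGGTGG	CAAC	705	o	o	o
gag	+	CAG	TTCAGGTTAAGAAGGGACCTTGG	TCAG	83	o	o	o
gag	+	CAG	GCAGACACTCTTCACAGCCGAGG	CAGA	780	x	x	x
gag	+	CAG	CCAGAAAGCCTCAGTGGCCCTGG	CAGA	1122	o	o	o
gag	+	CAG	TCAGAGACTGGAAGGGTTACAGG	CAGA	1185	o	o	o
gag	+	CGA	GCGAGAGAGAATTCTGTTAGAGG	CGAG	804	o	o	x
pol	+	CAA	TCAAGATATACAGTCCTGGTTGG	CAAG	126	o	o	x
pol	+	CAA	CCCAAACCCTAGGACCATGGAGG	CCAA	1214	o	o	x
pol	+	CAG	ACAGTACCCCTTGAGTAGAGAGG	CAGT	255	o	o	o
pol	+	CAG	GACAGTACACCCTAGAAGACTGG	ACAG	2105	o	o	o
pol	+	CAG	CCAGTTCTCTGAGACTCCGGAGG	CAGT	2148	o	o	o
pol	+	CGA	AGCGATGGCTGACGGAGGCACGG	GCGA	899	o	o	o
pol	+	CGA	TCCGAGATTTGGAATACCTAAGG	CCGA	2582	x	o	o
pol	-	CCA	ACCAGTTCCGTTCAGGCGGGAGG	CCAG	483	o	o	x
pol	-	TCA	CTTCAGTTGAATAACCTGTGGGG	TTCA	206	o	o	x
pol	-	CTA	TTCTAAGCAGTCCTGTTTGGTGG	TCTA	761	o	o	o
pol	-	CTA	TTCTAGGGTGTACTGTCGTCTGG	TCTA	2099	o	o	o
env	+	CAG	AACAGGAAAATATTCAAAAGTGG	ACAG	581	x	o	x
env	+	CAG	ACCAGGGGTGGTTTGAAGGATGG	CCAG	1751	o	o	x
env	+	CGA	CCGAGTGTACTACCATCCTGAGG	CGAG	1308	x	o	x
env	-	CTA	GTCTATAAGGCGTTTACTACTGG	TCTA	122	x	o	x
env	-	CCA	GACCATGACACAGAAATCTTTGG	ACCA	1274	x	o	x
env	-	CCA	ACCATCCTTCAAACCACCCCTGG	CCAT	1752	o	o	x
env	-	CCA	ACCCACTCGTTCTCTAACAAAGG	CCCA	1883	x	x	x
env	-	TCA	CGTCAGAGCAGAAAGCAGGGTGG	GTCA	1796	o	o	x
env	-	CTA	TCCTATGCATGTCCCCTTCCCGG	CCTA	1100	x	o	x
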