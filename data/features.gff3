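##gff-version 3
chr1	simdata	gene	31242	35242	.	+	.	ID=gene00
chr1	simdata	gene	93727	97727	.	+	.	ID=gene01
chr1	simdata	gene	156213	160213	.	+	.	ID=gene02
chr1	simdata	gene	218698	222698	.	+	.	ID=gene03
chr2	simdata	gene	31232	35232	.	+	.	ID=gene04
chr2	simdata	gene	93698	97698	.	+	.	ID=gene05
chr2	simdata	gene	156163	160163	.	+	.	ID=gene06
chr2	simdata	gene	218629	222629	.	+	.	ID=gene07
chr2	simdata	gene	202000	208000	.	+	.	ID=gene08
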