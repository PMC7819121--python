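name	consensus	class
ARE	AAACCA	abiotic
DRE1	ACCGAGA	abiotic
LTR	CCGAAA	abiotic
MBS	CAACTG	abiotic
MYC	CATTTG	abiotic
STRE	AGGGG	abiotic
TC-rich repeats	GTTTTCTTAC	abiotic
WRE3	CCACCT	abiotic
WUN-motif	AAATTTCCT	abiotic
ABRE	ACGTG	hormone
AuxRR-core	GGTCCAT	hormone
CGTCA-motif	CGTCA	hormone
ERE	ATTTCAAA	hormone
GARE-motif	TCTGTTG	hormone
P-box	CCTTTTG	hormone
TATC-box	TATCCCA	hormone
TCA-element	CCATCTTTTT	hormone
TGACG-motif	TGACG	hormone
TGA-element	AACGAC	hormone
AACA-motif	AACAAAC	growth
AT-rich element	ATAGAAATCAA	growth
CAT-box	GCCACT	growth
circadian	CAANNNNATC	growth
GCN4-motif	TGAGTCA	growth
HD-Zip 1	CAATWATTG	growth
MBSI	AAAAAACCGTTA	growth
MYB	CAACCA	growth
O2-site	GATGACATGG	growth
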