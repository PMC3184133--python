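# Published dumbbell decoy pairs (5'->3').  `core` is the declared CRE unit
# used for substring verification; `tandem` marks pairs whose ODN1 is an
# exact 5'-anchored tandem repeat of the core.
name	core	tandem	odn1	odn2
Evi-1	gataa	false	tttatcttggctgtttaccttgtctgcttggtttttccaag	cagacaaggtaaacagccaagataaaccgtctttttgacgg
FTS-1	tgattgatcct	true	tgattgatccttgattgatcctcttggtttttccaag	aggatcaatcaaggatcaatcaccgtctttttgacgg
SRY	acttttgtttttt	true	acttttgttttttacttttgttttttcttggtttttccaag	aaaaaacaaaagtaaaaaacaaaagtccgtctttttgacgg
GC-Box	ccccgcccc	false	ggccccgccccggtgccccgcccctgcttggtttttccaag	accggggcggggccaccggggcggggccccgtctttttgacgg
DB-control	actg	true	actgactgactgactgactgactgcttggtttttccaag	cagtcagtcagtcagtcagtcagtccgtctttttgacgg
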