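# Core cell-cycle / cell-fate regulatory interactions in Caulobacter crescentus
# (13 regulators, 27 directed signed interactions; evidence = PubMed ID)
regulator	target	sign	mechanism	evidence
CtrA	GcrA	negative	transcription	12445780
CtrA	DnaA	positive	transcription	12445780
CtrA	CcrM	positive	transcription	12445780
CtrA	SciP	positive	transcription	12445780
CtrA	CtrA	dual	transcription	12445780
GcrA	DnaA	negative	transcription	15087506
GcrA	CtrA	positive	transcription	15087506
DnaA	GcrA	positive	transcription	16395331
DnaA	SciP	negative	transcription	16395331
DnaA	DnaA	negative	transcription	16395331
CcrM	DnaA	positive	methylation	20472802
CcrM	CtrA	negative	methylation	20472802
CcrM	CcrM	negative	methylation	20472802
SciP	CtrA	negative	transcription	20472802
SciP	CcrM	negative	transcription	20472802
DivK	DivJ	positive	phosphorylation	7664732
DivK	PleC	negative	dephosphorylation	7664732
DivK	DivL	dual	binding	7664732
DivJ	DivK	positive	phosphorylation	20472802
PleC	DivK	negative	dephosphorylation	20472802
PleC	DivJ	negative	dephosphorylation	20472802
DivL	CckA	positive	binding	16547034
CckA	ChpT	dual	phosphorylation	10199407
ChpT	CtrA	positive	phosphorylation	20472802
ChpT	CpdR	dual	phosphorylation	20472802
CpdR	ClpXP_RcdA	dual	complex_assembly	20472802
ClpXP_RcdA	CtrA	negative	proteolysis	16829582
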