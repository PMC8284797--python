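# Experimentally validated KIR receptor / HLA ligand-group interactions.
interaction	kir_gene	ligand_variable
KIR2DL1_C2	KIR2DL1	C2
KIR2DL2_C1	KIR2DL2	C1
KIR2DL3_C1	KIR2DL3	C1
KIR2DS1_C2	KIR2DS1	C2
KIR2DS2_C1	KIR2DS2	C1
KIR3DL1_Bw4	KIR3DL1	Bw4
KIR3DS1_Bw4	KIR3DS1	Bw4
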