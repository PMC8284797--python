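# name=g_groups
# resolution=3
# Example G-group table (alleles sharing nucleotide sequence across the
# peptide-binding-domain exons); replace with a release-matched table for
# production use.
A*01:01:01G	A*01:01:01
A*01:01:01G	A*01:04:01
A*02:01:01G	A*02:01:01
A*02:01:01G	A*02:01:02
A*02:01:01G	A*02:09:01
B*07:02:01G	B*07:02:01
B*07:02:01G	B*07:44:01
C*07:02:01G	C*07:02:01
C*07:02:01G	C*07:50:01
DQB1*03:01:01G	DQB1*03:01:01
DQB1*03:01:01G	DQB1*03:01:04
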