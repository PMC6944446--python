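# Human codon-usage reference (counts per million codons).
# Derived from the classic GenBank-aggregate human codon usage summary
# (per-thousand frequencies, Kazusa-style), scaled by 1000.
# The published table rounds Gly GGA and GGG to the same per-thousand value
# (16.5); at that precision their order relative to the Gly family mean is
# unresolved. The tie is resolved here as GGA marginally above and GGG
# marginally below the family mean (total preserved), the resolution
# consistent with the printed human low-usage codon audit.
codon	amino_acid	count
TTT	F	17600
TTC	F	20300
TTA	L	7700
TTG	L	12900
CTT	L	13200
CTC	L	19600
CTA	L	7200
CTG	L	39600
ATT	I	16000
ATC	I	20800
ATA	I	7500
ATG	M	22000
GTT	V	11000
GTC	V	14500
GTA	V	7100
GTG	V	28100
TCT	S	15200
TCC	S	17700
TCA	S	12200
TCG	S	4400
CCT	P	17500
CCC	P	19800
CCA	P	16900
CCG	P	6900
ACT	T	13100
ACC	T	18900
ACA	T	15100
ACG	T	6100
GCT	A	18400
GCC	A	27700
GCA	A	15800
GCG	A	7400
TAT	Y	12200
TAC	Y	15300
TAA	*	1000
TAG	*	800
CAT	H	10900
CAC	H	15100
CAA	Q	12300
CAG	Q	34200
AAT	N	17000
AAC	N	19100
AAA	K	24400
AAG	K	31900
GAT	D	21800
GAC	D	25100
GAA	E	29000
GAG	E	39600
TGT	C	10600
TGC	C	12600
TGA	*	1600
TGG	W	13200
CGT	R	4500
CGC	R	10400
CGA	R	6200
CGG	R	11400
AGT	S	12100
AGC	S	19500
AGA	R	12200
AGG	R	12000
GGT	G	10800
GGC	G	22200
GGA	G	16520
GGG	G	16480
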