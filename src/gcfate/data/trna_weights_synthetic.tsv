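# Synthetic per-codon tRNA weights (tAI convention: max 1).
# These are NOT measured amino-acylated tRNA abundances: they are a
# synthetic stand-in derived by scaling the bundled human codon-usage
# frequencies to a maximum of 1 (floored at 0.02), adequate for testing
# the geometric-mean adaptation score, not for biological inference.
codon	weight
AAA	0.6162
AAC	0.4823
AAG	0.8056
AAT	0.4293
ACA	0.3813
ACC	0.4773
ACG	0.1540
ACT	0.3308
AGA	0.3081
AGC	0.4924
AGG	0.3030
AGT	0.3056
ATA	0.1894
ATC	0.5253
ATG	0.5556
ATT	0.4040
CAA	0.3106
CAC	0.3813
CAG	0.8636
CAT	0.2753
CCA	0.4268
CCC	0.5000
CCG	0.1742
CCT	0.4419
CGA	0.1566
CGC	0.2626
CGG	0.2879
CGT	0.1136
CTA	0.1818
CTC	0.4949
CTG	1.0000
CTT	0.3333
GAA	0.7323
GAC	0.6338
GAG	1.0000
GAT	0.5505
GCA	0.3990
GCC	0.6995
GCG	0.1869
GCT	0.4646
GGA	0.4172
GGC	0.5606
GGG	0.4162
GGT	0.2727
GTA	0.1793
GTC	0.3662
GTG	0.7096
GTT	0.2778
TAC	0.3864
TAT	0.3081
TCA	0.3081
TCC	0.4470
TCG	0.1111
TCT	0.3838
TGC	0.3182
TGG	0.3333
TGT	0.2677
TTA	0.1944
TTC	0.5126
TTG	0.3258
TTT	0.4444
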