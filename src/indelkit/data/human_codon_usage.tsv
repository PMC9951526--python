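# Human codon usage (relative synonymous codon fractions, GenBank-derived
# averages rounded to two decimals; normalized per amino acid on load).
# columns: amino_acid	codon	fraction
A	GCC	0.40
A	GCT	0.26
A	GCA	0.23
A	GCG	0.11
R	CGG	0.21
R	AGA	0.21
R	AGG	0.20
R	CGC	0.19
R	CGA	0.11
R	CGT	0.08
N	AAC	0.53
N	AAT	0.47
D	GAC	0.54
D	GAT	0.46
C	TGC	0.55
C	TGT	0.45
Q	CAG	0.75
Q	CAA	0.25
E	GAG	0.58
E	GAA	0.42
G	GGC	0.34
G	GGA	0.25
G	GGG	0.25
G	GGT	0.16
H	CAC	0.58
H	CAT	0.42
I	ATC	0.47
I	ATT	0.36
I	ATA	0.17
L	CTG	0.40
L	CTC	0.20
L	CTT	0.13
L	TTG	0.13
L	TTA	0.07
L	CTA	0.07
K	AAG	0.57
K	AAA	0.43
M	ATG	1.00
F	TTC	0.54
F	TTT	0.46
P	CCC	0.33
P	CCT	0.29
P	CCA	0.27
P	CCG	0.11
S	AGC	0.24
S	TCC	0.22
S	TCT	0.18
S	TCA	0.15
S	AGT	0.15
S	TCG	0.06
T	ACC	0.36
T	ACA	0.28
T	ACT	0.24
T	ACG	0.12
W	TGG	1.00
Y	TAC	0.56
Y	TAT	0.44
V	GTG	0.46
V	GTC	0.24
V	GTT	0.18
V	GTA	0.12
*	TGA	0.47
*	TAA	0.30
*	TAG	0.23
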