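# Acid dissociation constants (pKa) for the ionizable groups of a peptide,
# Bjellqvist set.  "Nterm"/"Cterm" are the free alpha-amino and alpha-carboxyl
# termini; single letters are side chains.  sign: +1 groups are basic
# (protonated below their pKa), -1 groups are acidic.
group	pka	sign
Nterm	7.50	+1
K	10.00	+1
R	12.00	+1
H	5.98	+1
Cterm	3.55	-1
D	4.05	-1
E	4.45	-1
C	9.00	-1
Y	10.00	-1
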