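# nearest-neighbor RNA:DNA hybrid dG37 (kcal/mol), Sugimoto 1995
# key: 5'->3' DNA coding-strand dinucleotide (RNA step = same with T->U)
step	dg_kcal_mol
AA	-1.0
AC	-2.1
AG	-1.8
AT	-0.9
CA	-0.9
CC	-2.1
CG	-1.7
CT	-0.9
GA	-1.3
GC	-2.7
GG	-2.9
GT	-1.1
TA	-0.6
TC	-1.5
TG	-1.6
TT	-0.2
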