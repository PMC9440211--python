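# SYNTHETIC dinucleotide stiffness table (arbitrary persistence-length units)
# additive stand-in following published stiffness trends; not a measured dataset
step	stiffness
AA	1.15
AC	0.95
AG	0.90
AT	1.10
CA	0.65
CC	1.00
CG	0.70
CT	0.90
GA	0.85
GC	0.90
GG	1.00
GT	0.95
TA	0.60
TC	0.85
TG	0.65
TT	1.15
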