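# Neighbor correction factors for backbone amide hydrogen exchange,
# log10 scale, poly-DL-alanine basis, D2O solvent.
# Values after Bai, Milne, Mayne & Englander, Proteins 17:75-86 (1993),
# Table II (side-chain inductive/steric effects on amide exchange).
# Convention: the observed amide of residue i is corrected by
#   10^(acid_left[res_i] + acid_right[res_{i-1}])  (acid channel)
#   10^(base_left[res_i] + base_right[res_{i-1}])  (base and water channels)
# i.e. the "left" column is the effect of a side chain on the amide on its
# N-terminal side (the residue's own NH), the "right" column its effect on
# the following residue's NH.
# Asp/Glu rows are the deprotonated (carboxylate) forms, valid for the
# pD 5-7 range this package targets; His is the protonated form.
# N_TERM applies as an extra *right*-type factor on the amide of residue 2
# (the free alpha-amino group precedes it); C_TERM applies as an extra
# *left*-type factor on the last residue's amide (carboxylate form).
residue	acid_left	acid_right	base_left	base_right
A	0.00	0.00	0.00	0.00
R	-0.59	-0.32	0.08	0.22
N	-0.58	-0.13	0.49	0.32
D	0.90	0.58	0.10	-0.18
C	-0.54	-0.46	0.62	0.55
G	-0.22	0.22	0.27	0.17
Q	-0.47	-0.27	0.06	0.20
E	-0.90	0.31	-0.11	-0.15
H	-0.80	-0.51	0.80	0.83
I	-0.91	-0.59	-0.73	-0.23
L	-0.57	-0.13	-0.58	-0.21
K	-0.56	-0.29	-0.04	0.12
M	-0.64	-0.28	-0.01	0.11
F	-0.52	-0.43	-0.24	0.06
P	0.00	-0.19	0.00	-0.24
S	-0.44	-0.39	0.37	0.30
T	-0.79	-0.47	-0.07	0.20
W	-0.40	-0.44	-0.41	-0.11
Y	-0.41	-0.37	-0.27	0.05
V	-0.74	-0.30	-0.70	-0.14
N_TERM	0.00	-1.32	0.00	1.62
C_TERM	0.96	0.00	-1.80	0.00
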