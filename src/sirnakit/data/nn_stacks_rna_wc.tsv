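# RNA Watson-Crick nearest-neighbor stacking parameters at 37 C
# (Xia et al. 1998, Biochemistry 37:14719-14735), symmetry-expanded from
# the 10 unique stacks to all 16 dinucleotide steps.
# step notation: top strand 5'->3' / bottom strand 3'->5' (aligned complement)
# dG37, dH in kcal/mol; dS in cal/(mol K). Duplex initiation and terminal
# AU penalties are deliberately excluded: whole-duplex dG here is strictly
# the sum of the 18 internal stacks of a 19-bp duplex.
step	dG37	dH	dS
AA/UU	-0.93	-6.82	-19.0
AC/UG	-2.24	-11.40	-29.5
AG/UC	-2.08	-10.48	-27.1
AU/UA	-1.10	-9.38	-26.7
CA/GU	-2.11	-10.44	-26.9
CC/GG	-3.26	-13.39	-32.7
CG/GC	-2.36	-10.64	-26.7
CU/GA	-2.08	-10.48	-27.1
GA/CU	-2.35	-12.44	-32.5
GC/CG	-3.42	-14.88	-36.9
GG/CC	-3.26	-13.39	-32.7
GU/CA	-2.24	-11.40	-29.5
UA/AU	-1.33	-7.69	-20.5
UC/AG	-2.35	-12.44	-32.5
UG/AC	-2.11	-10.44	-26.9
UU/AA	-0.93	-6.82	-19.0
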