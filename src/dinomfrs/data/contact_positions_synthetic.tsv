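# Synthetic stand-in curation of the 31 antigen-contact amino-acid
# positions of the MHC class I alpha-1/alpha-2 domains (IPD numbering).
# Composed from the canonical peptide-binding-groove residues of class I
# structures plus every group-diagnostic contact residue used by this
# package; pocket labels are approximate (A-F).
# position	pocket
59	A
62	A
65	A
69	A
73	C
74	C
76	C
77	C
80	C
81	C
84	C
88	D
91	D
95	D
97	D
99	D
114	E
116	E
118	E
122	E
143	F
146	F
152	F
155	F
156	F
159	F
161	A
170	A
180	B
181	B
186	B
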