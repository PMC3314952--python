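# Per-residue property table.
# rg_A: side-chain radius of gyration (Levitt 1976), Angstrom. The proline value is the
#   raw literature value; the default loader raises it to 2.0 A to account for the
#   restriction of conformational space by ring closure (applied once, at construction).
# lambda: persistence length for segmental motion, residues (2 for Ala/Gly, 7 otherwise).
# aabuf: average area buried upon folding (Rose et al. 1985), Angstrom^2.
residue	rg_A	lambda	aabuf
A	0.77	2	86.6
R	2.38	7	162.2
N	1.45	7	103.3
D	1.43	7	97.8
C	1.22	7	132.3
Q	1.75	7	119.2
E	1.77	7	113.9
G	0.58	2	62.9
H	1.78	7	155.8
I	1.56	7	158.0
L	1.54	7	164.1
K	2.08	7	115.5
M	1.80	7	172.9
F	1.90	7	194.1
P	1.25	7	92.9
S	1.08	7	85.6
T	1.24	7	106.5
W	2.21	7	224.6
Y	2.13	7	177.7
V	1.29	7	141.0
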