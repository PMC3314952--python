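# Random-coil chemical-shift reference (Wishart-style consensus values, ppm).
# Replaceable: pass any table with the same columns to RandomCoilReference.from_tsv.
# Gly has no CB; Pro has no backbone amide (N/HN omitted).
residue	nucleus	shift_ppm
A	CA	52.5
A	CB	19.1
A	CO	177.8
A	HA	4.32
A	N	123.8
A	HN	8.24
R	CA	56.0
R	CB	30.9
R	CO	176.3
R	HA	4.34
R	N	120.5
R	HN	8.23
N	CA	53.1
N	CB	38.9
N	CO	175.2
N	HA	4.74
N	N	118.7
N	HN	8.40
D	CA	54.2
D	CB	41.1
D	CO	176.3
D	HA	4.64
D	N	120.4
D	HN	8.34
C	CA	58.2
C	CB	28.0
C	CO	174.6
C	HA	4.55
C	N	118.8
C	HN	8.32
Q	CA	55.7
Q	CB	29.4
Q	CO	176.0
Q	HA	4.34
Q	N	119.8
Q	HN	8.32
E	CA	56.6
E	CB	29.9
E	CO	176.6
E	HA	4.35
E	N	120.2
E	HN	8.42
G	CA	45.1
G	CO	174.9
G	HA	3.96
G	N	108.8
G	HN	8.33
H	CA	55.0
H	CB	29.0
H	CO	174.1
H	HA	4.73
H	N	118.2
H	HN	8.42
I	CA	61.1
I	CB	38.8
I	CO	176.4
I	HA	4.17
I	N	119.9
I	HN	8.00
L	CA	55.1
L	CB	42.4
L	CO	177.6
L	HA	4.34
L	N	121.8
L	HN	8.16
K	CA	56.2
K	CB	33.1
K	CO	176.6
K	HA	4.32
K	N	120.4
K	HN	8.29
M	CA	55.4
M	CB	33.7
M	CO	176.3
M	HA	4.48
M	N	119.6
M	HN	8.28
F	CA	57.7
F	CB	39.6
F	CO	175.8
F	HA	4.62
F	N	120.3
F	HN	8.30
P	CA	63.3
P	CB	32.1
P	CO	177.3
P	HA	4.42
S	CA	58.3
S	CB	63.8
S	CO	174.6
S	HA	4.47
S	N	115.7
S	HN	8.31
T	CA	61.8
T	CB	69.8
T	CO	174.7
T	HA	4.35
T	N	113.6
T	HN	8.15
W	CA	57.5
W	CB	29.6
W	CO	176.1
W	HA	4.66
W	N	121.3
W	HN	8.25
Y	CA	57.9
Y	CB	38.8
Y	CO	175.9
Y	HA	4.55
Y	N	120.3
Y	HN	8.12
V	CA	62.2
V	CB	32.9
V	CO	176.3
V	HA	4.12
V	N	119.2
V	HN	8.03
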