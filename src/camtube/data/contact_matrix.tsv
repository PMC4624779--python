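# Residue-residue contact energies e_ij (Miyazawa-Jernigan 1996 style,
# attractive-contacts-negative), restricted to the hydrophobic set
# {A, V, L, I, M, F, W, C, Y}.  Entries are normalized at load time by
# |e(V,V)| so that B(Val,Val) = -1; all pairs involving a residue outside
# the hydrophobic set are zero.
C	C	-5.44
C	M	-4.99
C	F	-5.80
C	I	-5.50
C	L	-5.83
C	V	-4.96
C	W	-4.95
C	Y	-4.16
C	A	-3.57
M	M	-5.46
M	F	-6.56
M	I	-6.02
M	L	-6.41
M	V	-5.32
M	W	-5.55
M	Y	-4.91
M	A	-3.94
F	F	-7.26
F	I	-6.84
F	L	-7.28
F	V	-6.29
F	W	-6.16
F	Y	-5.66
F	A	-4.81
I	I	-6.54
I	L	-7.04
I	V	-6.05
I	W	-5.78
I	Y	-5.25
I	A	-4.58
L	L	-7.37
L	V	-6.48
L	W	-6.14
L	Y	-5.67
L	A	-4.91
V	V	-5.52
V	W	-5.18
V	Y	-4.62
V	A	-4.04
W	W	-5.06
W	Y	-4.66
W	A	-3.82
Y	Y	-4.17
Y	A	-3.36
A	A	-2.72
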