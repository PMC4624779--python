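# Self-avoiding sphere distance thresholds d (nm) per atom-kind pair.
# Pairs are unordered; kinds are N, H, CA, CB, C, O.
H	H	0.23
O	O	0.30
CA	CA	0.40
CA	CB	0.40
CA	C	0.35
CA	H	0.30
CA	N	0.35
CA	O	0.30
CB	CB	0.40
CB	C	0.32
CB	H	0.26
CB	N	0.32
CB	O	0.30
C	C	0.35
C	O	0.30
N	N	0.36
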