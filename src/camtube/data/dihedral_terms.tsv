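# Residue-specific Fourier terms for the CB-CA-N-C (phi-like) and
# CB-CA-C-N (psi-like) proper dihedrals: E = sum Vn (1 + cos(n*x - gamma)).
# columns: group	Vn(kJ/mol)	gamma(deg)	n
phi_broad	10.0	0	1
phi_broad	5.0	0	2
phi_broad	0.0	0	3
phi_helical	20.0	0	1
phi_helical	10.0	0	2
phi_helical	2.0	0	3
psi_mixed	1.0	0	1
psi_mixed	2.5	0	2
psi_mixed	1.0	0	3
psi_turn	10.0	0	1
psi_turn	5.0	0	2
psi_turn	2.5	0	3
psi_beta	0.0	0	1
psi_beta	2.5	0	2
psi_beta	2.5	0	3
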