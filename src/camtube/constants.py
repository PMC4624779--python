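"""Physical constants and the embedded backbone geometry table.

The six-site model (N, H, CA, CB, C, O per residue) delegates its bonded
geometry to a small fixed table of Amber-style backbone bond lengths and
angles.  The two hydrogen-bond avoidance radii used by the force field,
0.3197 nm and 0.2980 nm, equal 0.99 x (0.2 nm + C=O) and
0.99 x (0.2 nm + N-H) under exactly these bond lengths, which pins the
table's values.
"""

from __future__ import annotations

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 0.0083144621

# --- bond lengths (nm), constrained during dynamics -------------------------
BOND_N_H = 0.1010
BOND_C_O = 0.1229
BOND_N_CA = 0.1449
BOND_CA_C = 0.1522
BOND_C_N = 0.1335  # peptide bond
#: base CA-CB length; per-residue lengths are multiples of this value
BOND_CA_CB = 0.1526

# --- equilibrium angles (degrees) and force constants (kJ mol^-1 rad^-2) ----
# Harmonic: E = k/2 (theta - theta0)^2.
ANGLES = {
    ("N", "CA", "C"): (110.1, 527.0),
    ("CA", "C", "N"): (116.6, 585.0),
    ("C", "N", "CA"): (121.9, 418.0),
    ("CA", "C", "O"): (120.4, 669.0),
    ("O", "C", "N"): (122.9, 669.0),
    ("H", "N", "CA"): (119.05, 418.0),
    ("H", "N", "C"): (119.05, 418.0),
    ("N", "CA", "CB"): (110.4, 527.0),
    ("C", "CA", "CB"): (110.6, 527.0),
}

# --- planarity impropers (periodic, E = k (1 + cos(2 xi - 180deg))) ---------
#: trans-omega peptide-plane restraint (CA_i, C_i, N_i+1, CA_i+1)
K_IMPROPER_OMEGA = 40.0
#: carbonyl O planarity (CA_i, N_i+1, C_i, O_i)
K_IMPROPER_O = 43.9
#: amide H planarity (C_i-1, CA_i, N_i, H_i)
K_IMPROPER_H = 4.6

# --- masses (amu) -----------------------------------------------------------
ATOM_MASS = {"N": 14.007, "H": 1.008, "CA": 12.011, "C": 12.011, "O": 15.999}

#: full side-chain mass carried by the CB site (average masses of the R group)
SIDECHAIN_MASS = {
    "A": 15.035, "R": 100.144, "N": 58.060, "D": 59.045, "C": 47.095,
    "Q": 72.087, "E": 73.072, "H": 81.098, "I": 57.116, "L": 57.116,
    "K": 72.131, "M": 75.149, "F": 91.132, "P": 42.081, "S": 31.034,
    "T": 45.061, "W": 130.168, "Y": 107.131, "V": 43.089,
}

#: ideal hydrogen-bond O...H separation (nm)
HBOND_R0 = 0.2
#: avoidance radius C'...H = 0.99 * (r0 + C=O)
D_CH = round(0.99 * (HBOND_R0 + BOND_C_O), 4)  # 0.3197
#: avoidance radius O...N = 0.99 * (r0 + N-H)
D_ON = round(0.99 * (HBOND_R0 + BOND_N_H), 4)  # 0.2980
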