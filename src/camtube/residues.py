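"""Per-amino-acid properties of the six-site model.

Each of the 20 standard amino acids maps to exactly one :class:`AminoAcidSpec`
carrying its CB bond-length scale, hydrophobicity flag and dihedral-group
membership.  Glycine is the only residue without a CB site.
"""

from __future__ import annotations

from dataclasses import dataclass

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

# CA-CB length multipliers relative to the base Amber CA-CB bond.
# Residues not listed keep the unscaled bond (Ala); Gly has no CB.
CBETA_SCALE = {
    "A": 1.0,
    "V": 1.5, "P": 1.5, "T": 1.5, "S": 1.5, "C": 1.5,
    "D": 2.0, "I": 2.0, "L": 2.0, "N": 2.0,
    "F": 2.25,
    "E": 2.5, "Q": 2.5, "M": 2.5, "H": 2.5,
    "Y": 3.0, "W": 3.0,
    "K": 4.0, "R": 4.0,
}

#: residues whose CB pairs feel the hydrophobic contact potential
HYDROPHOBIC = frozenset("AVLIMFWCY")

# Dihedral-group membership for the CB-CA-N-C (phi-like) term.
PHI_GROUP = {}
for _aa in "RNDCHILMFSTWYV":
    PHI_GROUP[_aa] = "phi_broad"
for _aa in "AQEKP":
    PHI_GROUP[_aa] = "phi_helical"

# Dihedral-group membership for the CB-CA-C-N (psi-like) term.
PSI_GROUP = {}
for _aa in "RCELKMSW":
    PSI_GROUP[_aa] = "psi_mixed"
for _aa in "NDHP":
    PSI_GROUP[_aa] = "psi_turn"
for _aa in "AQIFTYV":
    PSI_GROUP[_aa] = "psi_beta"


@dataclass(frozen=True)
class AminoAcidSpec:
    """Static per-residue parameters of the coarse-grained model."""

    code: str
    cbeta_scale: float
    has_cbeta: bool
    is_hydrophobic: bool
    dihedral_group_phi: str | None
    dihedral_group_psi: str | None


def amino_acid_spec(code: str) -> AminoAcidSpec:
    """Resolve a one-letter code to its :class:`AminoAcidSpec`.

    Raises ``ValueError`` for anything outside the 20 standard residues.
    """
    if code not in ONE_TO_THREE:
        raise ValueError(f"unknown amino-acid code {code!r}")
    if code == "G":
        return AminoAcidSpec("G", 0.0, False, False, None, None)
    return AminoAcidSpec(
        code=code,
        cbeta_scale=CBETA_SCALE[code],
        has_cbeta=True,
        is_hydrophobic=code in HYDROPHOBIC,
        dihedral_group_phi=PHI_GROUP[code],
        dihedral_group_psi=PSI_GROUP[code],
    )
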