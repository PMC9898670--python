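"""Residue-level physical constants.

Masses are average (isotope-abundance weighted) residue masses in Da, i.e. the
amino-acid mass minus one water; they are the quantities that add up along a
peptide chain.  Volumes are amino-acid residue volumes in A^3 from the three
classical determinations -- Cohn & Edsall (1943, densitometry), Zamyatnin
(1972, solution volumes) and Chothia (1975, protein crystal interiors) -- and
the consensus volume used for partial-specific-volume work is their mean.
That consensus lineage is the basis of composition-based v-bar calculators
for solution hydrodynamics.

Hydroxyproline (one-letter code O, three-letter HYP) carries its true mass
(Pro + O) in mass bookkeeping, while volume work substitutes Pro's parameters
because the volume tables only cover the standard twenty residues.
"""

from __future__ import annotations

# 1 A^3/molecule = 0.6022 ml/mol  (Avogadro constant x 1e-24)
A3_TO_ML_PER_MOL = 0.6022140857

WATER_MASS = 18.0153          # Da, chain-terminal H2O of an unblocked peptide
ACETYL_MASS_INCREMENT = 42.0367   # Da, N-terminal H -> CH3CO
AMIDE_MASS_INCREMENT = -0.9847    # Da, C-terminal OH -> NH2
WATER_VOLUME = WATER_MASS / A3_TO_ML_PER_MOL * 1.0   # A^3 at v-bar(water)=1 ml/g

ONE_TO_THREE = {
    "G": "GLY", "A": "ALA", "S": "SER", "P": "PRO", "V": "VAL",
    "T": "THR", "C": "CYS", "L": "LEU", "I": "ILE", "N": "ASN",
    "D": "ASP", "Q": "GLN", "K": "LYS", "E": "GLU", "M": "MET",
    "H": "HIS", "F": "PHE", "R": "ARG", "Y": "TYR", "W": "TRP",
    "O": "HYP",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

# Average residue masses, Da
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
    "O": 113.1161,
}

# Cohn & Edsall (1943) partial specific volumes, ml/g (per residue)
_COHN_EDSALL_VBAR = {
    "A": 0.74, "R": 0.70, "N": 0.62, "D": 0.60, "C": 0.63, "Q": 0.67,
    "E": 0.66, "G": 0.64, "H": 0.67, "I": 0.90, "L": 0.90, "K": 0.82,
    "M": 0.75, "F": 0.77, "P": 0.76, "S": 0.63, "T": 0.70, "W": 0.74,
    "Y": 0.71, "V": 0.86,
}

# Zamyatnin (1972) residue volumes, A^3
_ZAMYATNIN_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 117.7, "D": 111.1, "C": 108.5, "Q": 143.9,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}

# Chothia (1975) mean volumes of buried residues in crystals, A^3
_CHOTHIA_VOLUME = {
    "A": 91.5, "R": 180.8, "N": 135.2, "D": 113.6, "C": 117.7, "Q": 161.1,
    "E": 140.6, "G": 66.4, "H": 167.3, "I": 168.8, "L": 167.9, "K": 176.2,
    "M": 170.8, "F": 203.4, "P": 129.3, "S": 99.1, "T": 122.1, "W": 237.6,
    "Y": 203.6, "V": 141.7,
}


def _consensus() -> dict[str, float]:
    out = {}
    for aa, vbar in _COHN_EDSALL_VBAR.items():
        v_ce = vbar * RESIDUE_MASS[aa] / A3_TO_ML_PER_MOL
        out[aa] = (v_ce + _ZAMYATNIN_VOLUME[aa] + _CHOTHIA_VOLUME[aa]) / 3.0
    return out


#: Consensus crystallographic/densitometric residue volumes, A^3.
#: Hydroxyproline is deliberately absent: v-bar work substitutes Pro.
RESIDUE_VOLUME = _consensus()

#: Heavy (non-hydrogen) side-chain atom names, in bonded order from CB.
#: Branches are given as (name, parent_name) where parent differs from the
#: previous atom.  Backbone N, CA, C, O are implicit.
SIDE_CHAIN_ATOMS: dict[str, list[tuple[str, str]]] = {
    "G": [],
    "A": [("CB", "CA")],
    "S": [("CB", "CA"), ("OG", "CB")],
    "C": [("CB", "CA"), ("SG", "CB")],
    "P": [("CB", "CA"), ("CG", "CB"), ("CD", "CG")],
    "O": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("OD1", "CG")],
    "V": [("CB", "CA"), ("CG1", "CB"), ("CG2", "CB")],
    "T": [("CB", "CA"), ("OG1", "CB"), ("CG2", "CB")],
    "L": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CD2", "CG")],
    "I": [("CB", "CA"), ("CG1", "CB"), ("CG2", "CB"), ("CD1", "CG1")],
    "N": [("CB", "CA"), ("CG", "CB"), ("OD1", "CG"), ("ND2", "CG")],
    "D": [("CB", "CA"), ("CG", "CB"), ("OD1", "CG"), ("OD2", "CG")],
    "Q": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("OE1", "CD"), ("NE2", "CD")],
    "E": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("OE1", "CD"), ("OE2", "CD")],
    "K": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("CE", "CD"), ("NZ", "CE")],
    "M": [("CB", "CA"), ("CG", "CB"), ("SD", "CG"), ("CE", "SD")],
    "H": [("CB", "CA"), ("CG", "CB"), ("ND1", "CG"), ("CD2", "CG"),
          ("CE1", "ND1"), ("NE2", "CD2")],
    "F": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"),
          ("CE1", "CD1"), ("CE2", "CD2"), ("CZ", "CE1")],
    "Y": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"),
          ("CE1", "CD1"), ("CE2", "CD2"), ("CZ", "CE1"), ("OH", "CZ")],
    "W": [("CB", "CA"), ("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"),
          ("NE1", "CD1"), ("CE2", "CD2"), ("CE3", "CD2"), ("CZ2", "CE2"),
          ("CZ3", "CE3"), ("CH2", "CZ2")],
    "R": [("CB", "CA"), ("CG", "CB"), ("CD", "CG"), ("NE", "CD"),
          ("CZ", "NE"), ("NH1", "CZ"), ("NH2", "CZ")],
}

SUPPORTED_RESIDUES = frozenset(ONE_TO_THREE)
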