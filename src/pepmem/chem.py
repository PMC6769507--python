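"""Chemical reference data: element masses, residue codes, side-chain masses.

Masses are standard atomic weights in amu. Side-chain masses are average
masses of the side chain (heavy atoms plus hydrogens) of each amino acid,
i.e. the residue mass in a chain minus the common backbone unit (56.04 amu,
the glycine residue minus its side-chain hydrogen).
"""

from __future__ import annotations

ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "ZN": 65.38,
    "BR": 79.904,
    "I": 126.904,
}

AA3_TO_1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3: dict[str, str] = {v: k for k, v in AA3_TO_1.items()}

PEPTIDE_RESNAMES = set(AA3_TO_1)
WATER_RESNAMES = {"HOH", "SOL", "WAT", "TIP", "TIP3", "SPC", "W"}
ION_RESNAMES = {"NA", "CL", "K", "MG", "ZN", "CA2", "NA+", "CL-", "IOD"}

# Average side-chain mass per residue type [amu]: residue chain mass - 56.04.
SIDECHAIN_MASSES: dict[str, float] = {
    "A": 15.03, "R": 100.14, "N": 58.06, "D": 59.04, "C": 47.10,
    "Q": 72.09, "E": 73.07, "G": 1.01, "H": 81.10, "I": 57.11,
    "L": 57.11, "K": 72.13, "M": 75.15, "F": 91.13, "P": 42.08,
    "S": 31.03, "T": 45.06, "W": 130.17, "V": 43.09, "Y": 107.13,
}

BACKBONE_ATOM_NAMES = {"N", "H", "H1", "H2", "H3", "HN", "CA", "HA", "HA1",
                       "HA2", "HA3", "C", "O", "OXT", "OT1", "OT2"}

# Guanidinium nitrogen naming follows PDB v3.
ARG_GUANIDINIUM_N = ("NE", "NH1", "NH2")
ARG_CZ = "CZ"

TRP_RING_ATOMS = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")


def element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name (first alphabetic character)."""
    for ch in name.strip():
        if ch.isalpha():
            if ch.upper() in ("H",) or (name.strip()[0].isdigit() and ch == "H"):
                return "H"
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


def mass_of_element(element: str) -> float:
    try:
        return ELEMENT_MASSES[element.upper()]
    except KeyError as exc:
        raise KeyError(f"no mass tabulated for element {element!r}") from exc


def infer_group(residue_name: str) -> str:
    """Classify a residue into {peptide, water, ion, lipid} by its name."""
    rn = residue_name.strip().upper()
    if rn in PEPTIDE_RESNAMES:
        return "peptide"
    if rn in WATER_RESNAMES:
        return "water"
    if rn in ION_RESNAMES:
        return "ion"
    return "lipid"
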