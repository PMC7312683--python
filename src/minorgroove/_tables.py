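"""Packaged reference data.

Base heavy-atom coordinates are given in the standard base-pair reference
frame (x toward the major groove, y along the long pair axis, base plane at
z = 0); they are the community-standard idealized base geometries used by
essentially every nucleic-acid geometry program.  The complementary strand-2
base of a Watson-Crick pair is obtained by a 180 degree rotation about x.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# residue-name dictionaries
# ---------------------------------------------------------------------------

AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: map from common PDB nucleotide-name dialects to the canonical codes
DNA_NAME_ALIASES: dict[str, str] = {
    "DA": "dA", "DC": "dC", "DG": "dG", "DT": "dT",
    "dA": "dA", "dC": "dC", "dG": "dG", "dT": "dT",
    "ADE": "dA", "CYT": "dC", "GUA": "dG", "THY": "dT",
}

#: bare-letter ribonucleotide-style names are accepted only when the residue
#: carries a deoxyribose (no O2' atom); see structure_io.classify_chains
BARE_DNA_ALIASES: dict[str, str] = {"A": "dA", "C": "dC", "G": "dG", "T": "dT"}

STANDARD_DNA: tuple[str, ...] = ("dA", "dC", "dG", "dT")

COMPLEMENT: dict[str, str] = {"A": "T", "T": "A", "G": "C", "C": "G"}

ONE_LETTER: dict[str, str] = {"dA": "A", "dC": "C", "dG": "G", "dT": "T"}

# ---------------------------------------------------------------------------
# groove reference atoms: base -> (minor-groove atom, major-groove atom)
# ---------------------------------------------------------------------------

REFERENCE_ATOMS: dict[str, tuple[str, str]] = {
    "dA": ("N3", "N6"),
    "dG": ("N3", "O6"),
    "dT": ("O2", "O4"),
    "dC": ("O2", "N4"),
}

# ---------------------------------------------------------------------------
# heavy-atom inventories per nucleotide (validation reference)
# ---------------------------------------------------------------------------

SUGAR_PHOSPHATE_ATOMS: tuple[str, ...] = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'",
)

#: the 5'-terminal residue of a chain routinely lacks these in PDB entries
OPTIONAL_5PRIME_ATOMS: frozenset[str] = frozenset({"P", "OP1", "OP2"})

BASE_ATOMS: dict[str, tuple[str, ...]] = {
    "dA": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "dG": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "dC": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "dT": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"),
}

#: legacy atom-name spellings normalized on parse
ATOM_NAME_ALIASES: dict[str, str] = {
    "O1P": "OP1", "O2P": "OP2", "C5M": "C7",
    "O5*": "O5'", "C5*": "C5'", "C4*": "C4'", "O4*": "O4'",
    "C3*": "C3'", "O3*": "O3'", "C2*": "C2'", "C1*": "C1'",
}

# ---------------------------------------------------------------------------
# standard reference-frame base geometry (heavy atoms incl. C1'), Å
# ---------------------------------------------------------------------------

STANDARD_BASE_COORDS: dict[str, dict[str, np.ndarray]] = {
    "dA": {
        "C1'": np.array([-2.479, 5.346, 0.0]),
        "N9": np.array([-1.291, 4.498, 0.0]),
        "C8": np.array([0.024, 4.897, 0.0]),
        "N7": np.array([0.877, 3.902, 0.0]),
        "C5": np.array([0.071, 2.771, 0.0]),
        "C6": np.array([0.369, 1.398, 0.0]),
        "N6": np.array([1.611, 0.909, 0.0]),
        "N1": np.array([-0.668, 0.532, 0.0]),
        "C2": np.array([-1.912, 1.023, 0.0]),
        "N3": np.array([-2.320, 2.290, 0.0]),
        "C4": np.array([-1.267, 3.124, 0.0]),
    },
    "dG": {
        "C1'": np.array([-2.477, 5.399, 0.0]),
        "N9": np.array([-1.289, 4.551, 0.0]),
        "C8": np.array([0.023, 4.962, 0.0]),
        "N7": np.array([0.870, 3.969, 0.0]),
        "C5": np.array([0.071, 2.833, 0.0]),
        "C6": np.array([0.424, 1.460, 0.0]),
        "O6": np.array([1.554, 0.955, 0.0]),
        "N1": np.array([-0.700, 0.641, 0.0]),
        "C2": np.array([-1.999, 1.087, 0.0]),
        "N2": np.array([-2.949, 0.139, 0.0]),
        "N3": np.array([-2.342, 2.364, 0.0]),
        "C4": np.array([-1.265, 3.177, 0.0]),
    },
    "dC": {
        "C1'": np.array([-2.477, 5.402, 0.0]),
        "N1": np.array([-1.285, 4.542, 0.0]),
        "C2": np.array([-1.472, 3.158, 0.0]),
        "O2": np.array([-2.628, 2.709, 0.0]),
        "N3": np.array([-0.391, 2.344, 0.0]),
        "C4": np.array([0.837, 2.868, 0.0]),
        "N4": np.array([1.875, 2.027, 0.0]),
        "C5": np.array([1.056, 4.275, 0.0]),
        "C6": np.array([-0.023, 5.068, 0.0]),
    },
    "dT": {
        "C1'": np.array([-2.481, 5.354, 0.0]),
        "N1": np.array([-1.284, 4.500, 0.0]),
        "C2": np.array([-1.462, 3.135, 0.0]),
        "O2": np.array([-2.562, 2.608, 0.0]),
        "N3": np.array([-0.298, 2.407, 0.0]),
        "C4": np.array([0.994, 2.897, 0.0]),
        "O4": np.array([1.944, 2.119, 0.0]),
        "C5": np.array([1.106, 4.338, 0.0]),
        "C7": np.array([2.466, 4.961, 0.0]),
        "C6": np.array([-0.024, 5.057, 0.0]),
    },
}

#: glycosidic nitrogen and the base atom defining the chi torsion
GLYCOSIDIC_ATOMS: dict[str, tuple[str, str]] = {
    "dA": ("N9", "C4"),
    "dG": ("N9", "C4"),
    "dC": ("N1", "C2"),
    "dT": ("N1", "C2"),
}

ELEMENT_FROM_NAME_FIRST_CHAR = {"C": "C", "N": "N", "O": "O", "P": "P", "S": "S"}


def element_of(atom_name: str) -> str:
    """Infer the element from a (normalized) heavy-atom name."""
    for ch in atom_name:
        if ch.isalpha():
            return ELEMENT_FROM_NAME_FIRST_CHAR.get(ch.upper(), ch.upper())
    return "X"


# ---------------------------------------------------------------------------
# hydrogen-bond chemistry tables (heavy-atom donors/acceptors)
# ---------------------------------------------------------------------------

#: protein side-chain donors: residue -> {donor atom: antecedent atom}
PROTEIN_SC_DONORS: dict[str, dict[str, str]] = {
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "LYS": {"NZ": "CE"},
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "TRP": {"NE1": "CD1"},
    "CYS": {"SG": "CB"},
}

PROTEIN_SC_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}

#: backbone donor/acceptor shared by all amino acids
PROTEIN_BB_DONOR: tuple[str, str] = ("N", "CA")  # donor, antecedent
PROTEIN_BB_ACCEPTOR: str = "O"

#: DNA base donors: base -> {donor atom: antecedent}
DNA_BASE_DONORS: dict[str, dict[str, str]] = {
    "dA": {"N6": "C6"},
    "dG": {"N1": "C6", "N2": "C2"},
    "dC": {"N4": "C4"},
    "dT": {"N3": "C2"},
}

DNA_BASE_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "dA": ("N1", "N3", "N7"),
    "dG": ("N3", "N7", "O6"),
    "dC": ("O2", "N3"),
    "dT": ("O2", "O4"),
}

#: DNA target-class taxonomy for interaction-mode reports
DNA_PHOSPHATE_ATOMS: frozenset[str] = frozenset({"OP1", "OP2", "O5'", "O3'", "P"})
DNA_DEOXYRIBOSE_OXYGENS: frozenset[str] = frozenset({"O4'"})


def dna_target_class(atom_name: str) -> str:
    """Classify a DNA heavy atom as base / deoxyribose / phosphate."""
    if atom_name in DNA_PHOSPHATE_ATOMS:
        return "phosphate"
    if atom_name in DNA_DEOXYRIBOSE_OXYGENS:
        return "deoxyribose"
    if atom_name in ("C1'", "C2'", "C3'", "C4'", "C5'"):
        return "deoxyribose"
    return "base"
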