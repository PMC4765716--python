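"""Amino-acid reference data and the packaged statistical contact potentials.

All residue-level knowledge used by the pipeline lives here: the twenty
3-letter codes, a hydropathy scale, formal charges, coarse chemical classes
used in pocket comparison, a default sequence composition, the 20x20
residue-residue contact potential that drives sequence design and
protein-protein interaction energies, and the 20x2 residue-nucleotide
potential used for protein-DNA energies.

The contact potential is a simple hydrophobicity-dominated form

    e(a, b) = -w_h * h(a) * h(b) + w_q * q(a) * q(b)

with h the Kyte-Doolittle hydropathy rescaled to [0, 1] and q the formal
charge.  Lower is more favourable: burying hydrophobic pairs is rewarded,
like-charge pairs are penalised, salt bridges are mildly rewarded.  The
absolute scale is arbitrary; thresholds on summed energies are therefore
configuration, not physics (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

ONE_LETTER: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Kyte-Doolittle hydropathy
KYTE_DOOLITTLE: dict[str, float] = {
    "ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5,
    "GLN": -3.5, "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5,
    "LEU": 3.8, "LYS": -3.9, "MET": 1.9, "PHE": 2.8, "PRO": -1.6,
    "SER": -0.8, "THR": -0.7, "TRP": -0.9, "TYR": -1.3, "VAL": 4.2,
}

# hydropathy rescaled to [0, 1]
HYDROPHOBICITY: dict[str, float] = {
    aa: (kd + 4.5) / 9.0 for aa, kd in KYTE_DOOLITTLE.items()
}

CHARGE: dict[str, float] = {aa: 0.0 for aa in AMINO_ACIDS}
CHARGE.update({"ARG": 1.0, "LYS": 1.0, "ASP": -1.0, "GLU": -1.0})

HYDROPHOBIC_SET = frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "CYS",
                             "PHE", "TRP", "TYR"})

# Coarse chemical classes used by the pocket-similarity score.
CHEMICAL_CLASS: dict[str, str] = {}
for _aa in ("ALA", "VAL", "LEU", "ILE", "MET", "CYS"):
    CHEMICAL_CLASS[_aa] = "hydrophobic"
for _aa in ("PHE", "TRP", "TYR"):
    CHEMICAL_CLASS[_aa] = "aromatic"
for _aa in ("SER", "THR", "ASN", "GLN", "HIS"):
    CHEMICAL_CLASS[_aa] = "polar"
for _aa in ("LYS", "ARG"):
    CHEMICAL_CLASS[_aa] = "positive"
for _aa in ("ASP", "GLU"):
    CHEMICAL_CLASS[_aa] = "negative"
for _aa in ("GLY", "PRO"):
    CHEMICAL_CLASS[_aa] = "special"

# Average globular-protein composition; sums to 1.
DEFAULT_COMPOSITION: dict[str, float] = {
    "ALA": 0.080, "ARG": 0.050, "ASN": 0.040, "ASP": 0.055, "CYS": 0.015,
    "GLN": 0.040, "GLU": 0.065, "GLY": 0.080, "HIS": 0.022, "ILE": 0.060,
    "LEU": 0.095, "LYS": 0.058, "MET": 0.024, "PHE": 0.040, "PRO": 0.047,
    "SER": 0.066, "THR": 0.054, "TRP": 0.011, "TYR": 0.030, "VAL": 0.068,
}

_W_HYDROPHOBIC = 1.0
_W_CHARGE = 0.4


def _build_contact_potential() -> np.ndarray:
    h = np.array([HYDROPHOBICITY[aa] for aa in AMINO_ACIDS])
    q = np.array([CHARGE[aa] for aa in AMINO_ACIDS])
    return -_W_HYDROPHOBIC * np.outer(h, h) + _W_CHARGE * np.outer(q, q)


#: 20x20 symmetric residue-residue contact potential (row/col order AMINO_ACIDS).
CONTACT_POTENTIAL: np.ndarray = _build_contact_potential()


def contact_energy(aa1: str, aa2: str) -> float:
    """Pairwise contact energy between two residues (lower = more favourable)."""
    return float(CONTACT_POTENTIAL[AA_INDEX[aa1], AA_INDEX[aa2]])


# Residue-nucleotide potential: per-contact terms against the phosphate site
# and the base-centroid site.  Arg/Lys-phosphate attraction and Asp/Glu-
# phosphate repulsion encode the electrostatics of the DNA backbone.
DNA_POTENTIAL: dict[str, tuple[float, float]] = {
    "ARG": (-1.2, -0.4), "LYS": (-1.0, -0.3), "HIS": (-0.4, -0.3),
    "SER": (-0.2, -0.1), "THR": (-0.2, -0.1), "ASN": (-0.2, -0.2),
    "GLN": (-0.2, -0.2), "TYR": (-0.1, -0.3), "TRP": (0.0, -0.3),
    "GLY": (0.0, 0.0), "ASP": (1.0, 0.2), "GLU": (1.0, 0.2),
    "ALA": (0.2, 0.0), "VAL": (0.2, 0.0), "LEU": (0.2, 0.0),
    "ILE": (0.2, 0.0), "MET": (0.2, 0.0), "PHE": (0.2, -0.1),
    "PRO": (0.2, 0.0), "CYS": (0.2, 0.0),
}


def dna_contact_energy(aa: str, site: str) -> float:
    """Energy of one residue-nucleotide contact; site is 'P' or 'B'."""
    p, b = DNA_POTENTIAL[aa]
    if site == "P":
        return p
    if site == "B":
        return b
    raise ValueError(f"unknown nucleotide site {site!r} (expected 'P' or 'B')")
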