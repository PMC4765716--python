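"""Protein-DNA complex assembly and scoring.

DNA is carried in a reduced two-site-per-nucleotide representation
(phosphate plus base centroid) on an ideal B-form duplex: rise 3.4 A and
twist 36 degrees per base pair, two antiparallel strands.  Putative
protein-DNA complexes are built by structurally aligning a protein onto
the protein of a DNA-bound template (the DNA stays fixed), then scored
with:

* E_DP — a residue-nucleotide contact energy (C-beta within 7 A of a
  phosphate or base centroid) from the packaged 20x2 potential, with
  favourable Arg/Lys-phosphate terms and a clash penalty; DNA is treated
  as a negatively charged, sequence-nonspecific partner;
* an interfacial TM-score (iTM) — the TM-score restricted to the
  template protein's DNA-interface residues, normalised by interface size;
* a DNA-binding propensity — interface log-odds against a non-DNA-binding
  surface background, as in :mod:`foldfunc.complexes`.

The default thresholds (E_DP < -10 attractive, iTM >= 0.4) are scale-
dependent configuration, with percentile calibration available.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from foldfunc import chem
from foldfunc.complexes import PropensityScore, binding_propensity, composition, \
    propensity_table, surface_residue_indices
from foldfunc.structure import AlignmentResult, Structure, structural_align, \
    tm_score

DNA_CONTACT_CUTOFF = 7.0   # A, residue C-beta to phosphate/base centroid
DNA_CLASH_DISTANCE = 3.5   # A, C-alpha to any nucleotide site
DNA_CLASH_PENALTY = 10.0
DEFAULT_E_ATTRACTIVE = -10.0
DEFAULT_ITM_CUT = 0.4
DEFAULT_E_REPULSIVE = 10.0

RISE = 3.4                  # A per base pair
TWIST = math.radians(36.0)  # per base pair
PHOSPHATE_RADIUS = 8.9      # A from the helix axis
BASE_RADIUS = 4.0
STRAND2_PHASE = math.radians(140.0)   # azimuthal offset of the second strand

_COMPLEMENT = {"DA": "DT", "DT": "DA", "DG": "DC", "DC": "DG"}


@dataclasses.dataclass
class DnaStructure:
    """Two antiparallel strands of (base, phosphate, base-centroid) sites."""

    bases: list[str]               # strand 1 then strand 2, 5'->3' each
    phosphates: np.ndarray         # (2n, 3)
    centroids: np.ndarray          # (2n, 3)

    def __post_init__(self) -> None:
        self.phosphates = np.asarray(self.phosphates, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(self.bases) % 2:
            raise ValueError("strand lengths must be equal")
        if not (np.all(np.isfinite(self.phosphates))
                and np.all(np.isfinite(self.centroids))):
            raise ValueError("non-finite DNA coordinates")

    @property
    def n_bp(self) -> int:
        return len(self.bases) // 2

    def site_coords(self) -> np.ndarray:
        """All contact sites: phosphates then centroids, (4n, 3)."""
        return np.vstack([self.phosphates, self.centroids])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "DnaStructure":
        return DnaStructure(list(self.bases),
                            self.phosphates @ rotation.T + translation,
                            self.centroids @ rotation.T + translation)


def build_bdna(n_bp: int, seed: int = 0) -> DnaStructure:
    """Ideal B-DNA duplex along the z axis with a random sequence."""
    if n_bp < 2:
        raise ValueError("need at least 2 base pairs")
    rng = np.random.Generator(np.random.PCG64(seed))
    strand1 = [str(rng.choice(("DA", "DT", "DG", "DC"))) for _ in range(n_bp)]
    strand2 = [_COMPLEMENT[b] for b in strand1[::-1]]
    k = np.arange(n_bp)
    ang1 = TWIST * k
    z = RISE * k
    p1 = np.column_stack([PHOSPHATE_RADIUS * np.cos(ang1),
                          PHOSPHATE_RADIUS * np.sin(ang1), z])
    c1 = np.column_stack([BASE_RADIUS * np.cos(ang1),
                          BASE_RADIUS * np.sin(ang1), z])
    # antiparallel partner strand: same base-pair planes, offset azimuth,
    # listed 5'->3' which runs opposite in z
    ang2 = (TWIST * k + STRAND2_PHASE)[::-1]
    z2 = z[::-1]
    p2 = np.column_stack([PHOSPHATE_RADIUS * np.cos(ang2),
                          PHOSPHATE_RADIUS * np.sin(ang2), z2])
    c2 = np.column_stack([BASE_RADIUS * np.cos(ang2),
                          BASE_RADIUS * np.sin(ang2), z2])
    return DnaStructure(strand1 + strand2, np.vstack([p1, p2]),
                        np.vstack([c1, c2]))


def dna_site_coords(dna: DnaStructure) -> np.ndarray:
    return dna.site_coords()


@dataclasses.dataclass
class DnaComplexTemplate:
    """A protein bound to a B-DNA duplex, with its contact interface."""

    protein: Structure
    dna: DnaStructure
    interface_pairs: list[tuple[int, int, str]] = dataclasses.field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.interface_pairs is None:
            self.interface_pairs = residue_nucleotide_contacts(self.protein, self.dna)

    @property
    def interface_residues(self) -> list[int]:
        return sorted({i for i, _, _ in self.interface_pairs})


def residue_nucleotide_contacts(protein: Structure, dna: DnaStructure,
                                cutoff: float = DNA_CONTACT_CUTOFF
                                ) -> list[tuple[int, int, str]]:
    """(residue, nucleotide, site) contacts; site is 'P' or 'B'.

    A residue's C-beta (C-alpha for Gly) within ``cutoff`` of a phosphate
    or base centroid counts as one contact with that site type.
    """
    inter = protein.interaction_coords()
    out: list[tuple[int, int, str]] = []
    for site_label, coords in (("P", dna.phosphates), ("B", dna.centroids)):
        tree = cKDTree(coords)
        for ri, hits in enumerate(tree.query_ball_point(inter, cutoff)):
            for nj in hits:
                out.append((int(ri), int(nj), site_label))
    return sorted(out)


@dataclasses.dataclass
class DnaPutativeComplex:
    """A protein placed onto a DNA-bound template."""

    protein: Structure            # placed in the template frame
    template: DnaComplexTemplate
    align: AlignmentResult
    clash_count: int
    e_dp: float | None = None
    itm_score: float | None = None
    label: str = ""


@dataclasses.dataclass
class DnaRejection:
    reason: str
    tm: float


def assemble_dna(protein: Structure, template: DnaComplexTemplate,
                 min_tm: float = 0.4) -> DnaPutativeComplex | DnaRejection:
    """Align a protein onto the template's protein; the DNA stays fixed."""
    if protein.n_residues < 20:
        raise ValueError("protein must have >= 20 residues")
    align = structural_align(protein, template.protein)
    if align.tm < min_tm:
        return DnaRejection("tm", align.tm)
    placed = protein.transformed(align.rotation, align.translation)
    sites = template.dna.site_coords()
    tree = cKDTree(sites)
    clashes = int(sum(len(lst) for lst in
                      tree.query_ball_point(placed.ca_coords(), DNA_CLASH_DISTANCE)))
    return DnaPutativeComplex(placed, template, align, clashes,
                              label=protein.label)


def dna_interaction_energy(c: DnaPutativeComplex) -> float:
    """E_DP: summed residue-nucleotide contact terms plus clash penalty."""
    contacts = residue_nucleotide_contacts(c.protein, c.template.dna)
    names = c.protein.residue_names()
    e = sum(chem.dna_contact_energy(names[ri], site) for ri, _, site in contacts)
    e += DNA_CLASH_PENALTY * c.clash_count
    c.e_dp = float(e)
    return c.e_dp


def interfacial_tm(c: DnaPutativeComplex,
                   template: DnaComplexTemplate | None = None) -> float:
    """TM-score over the template protein's DNA-interface residues.

    Distances are between the placed protein's mapped residues and the
    template protein's interface residues, normalised by interface size.
    """
    template = template or c.template
    iface = template.interface_residues
    if not iface:
        raise ValueError("template has an empty DNA interface")
    mapping = {b: a for a, b in c.align.mapping}
    placed_ca = c.protein.ca_coords()
    t_ca = template.protein.ca_coords()
    d = []
    for r in iface:
        m = mapping.get(r)
        if m is not None:
            d.append(np.linalg.norm(placed_ca[m] - t_ca[r]))
    if not d:
        c.itm_score = 0.0
        return 0.0
    c.itm_score = tm_score(np.asarray(d), len(iface))
    return c.itm_score


def dna_interface_names(c: DnaPutativeComplex) -> list[str]:
    """Residue identities at the assembled complex's own DNA interface."""
    contacts = residue_nucleotide_contacts(c.protein, c.template.dna)
    names = c.protein.residue_names()
    return [names[i] for i in sorted({ri for ri, _, _ in contacts})]


def estimate_dna_propensity_table(templates: Sequence[DnaComplexTemplate]
                                  ) -> dict[str, float]:
    """Log-odds of DNA-interface vs non-DNA-binding surface composition."""
    iface_names: list[str] = []
    surf_names: list[str] = []
    for t in templates:
        names = t.protein.residue_names()
        iface = set(t.interface_residues)
        iface_names.extend(names[i] for i in iface)
        surf_names.extend(names[i] for i in surface_residue_indices(t.protein)
                          if i not in iface)
    if not iface_names or not surf_names:
        raise ValueError("no interface/surface residues in the library")
    return propensity_table(composition(iface_names), composition(surf_names))


def dna_propensity_and_classify(complexes: Sequence[DnaPutativeComplex],
                                log_odds: Mapping[str, float],
                                e_cut: float = DEFAULT_E_ATTRACTIVE,
                                itm_cut: float = DEFAULT_ITM_CUT,
                                e_repulsive: float = DEFAULT_E_REPULSIVE,
                                bins: int = 20):
    """Attractive/repulsive classification, propensities and 2-D density.

    Attractive: E_DP < ``e_cut`` and iTM >= ``itm_cut``; repulsive:
    E_DP > ``e_repulsive``.  Propensity is the mean interface log-odds
    (same form as protein-protein binding propensity).  Histogram counts
    sum to the input size.
    """
    attractive = [c for c in complexes
                  if c.e_dp is not None and c.itm_score is not None
                  and c.e_dp < e_cut and c.itm_score >= itm_cut]
    repulsive = [c for c in complexes if c.e_dp is not None and c.e_dp > e_repulsive]
    propensities: list[PropensityScore] = []
    for c in complexes:
        iface = dna_interface_names(c)
        propensities.append(binding_propensity(iface, log_odds) if iface
                            else PropensityScore(0.0))
    if complexes:
        e = np.array([c.e_dp if c.e_dp is not None else 0.0 for c in complexes])
        itm = np.array([c.itm_score if c.itm_score is not None else 0.0
                        for c in complexes])
        hist, xe, ye = np.histogram2d(e, itm, bins=bins)
    else:
        hist, xe, ye = np.zeros((0, 0)), np.zeros(0), np.zeros(0)
    return attractive, repulsive, propensities, (hist, xe, ye)


# ---------------------------------------------------------------------------
# PDB export of the reduced DNA representation
# ---------------------------------------------------------------------------

def write_dna_pdb(dna: DnaStructure) -> str:
    """Nucleotides as P / CEN pseudo-atom HETATM records (chains C/D)."""
    lines = []
    serial = 1
    n = dna.n_bp
    for strand, chain_id in ((0, "C"), (1, "D")):
        for i in range(n):
            gi = strand * n + i
            base = dna.bases[gi]
            for name, coord, elem in (("P", dna.phosphates[gi], "P"),
                                      ("CEN", dna.centroids[gi], "C")):
                x, y, z = coord
                lines.append(
                    f"HETATM{serial:5d} {name:<4s}{base:>3s} {chain_id}{i + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2s}")
                serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
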