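"""Template-based dimer assembly and interface scoring.

Putative protein-protein complexes are built by structurally aligning two
monomers onto the chains of a native-like dimer template and applying the
alignment transforms.  A complex is kept only when both monomers align
well (TM-score) and cover more than half of the template's interface.
Accepted complexes are scored with:

* an inter-chain contact energy E_PP — the packaged residue-contact
  potential summed over interface contacts plus a 10.0 penalty per
  inter-chain C-alpha clash (< 3.5 A); lower is more favourable;
* an interface-similarity (IS-like) score — the fraction of template
  interface contacts reproduced, damped by interface RMSD — with a
  calibrated p-value;
* a binding-propensity score — the mean interface log-odds
  log(f_interface(aa)/f_surface(aa)) estimated from a template library;
  positive implies favourable binding.

Energy thresholds (the E_PP < -15 attractive and > +10 repulsive defaults)
are tied to the potential's scale and shipped as configuration together
with a percentile-calibration helper.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from foldfunc import chem
from foldfunc.calibration import TailCalibrator
from foldfunc.structure import (
    AlignmentResult,
    Structure,
    contact_pairs,
    contact_numbers,
    structural_align,
)

CLASH_DISTANCE = 3.5       # A, inter-chain C-alpha
CLASH_PENALTY = 10.0       # per clash, added to E_PP
DEFAULT_E_ATTRACTIVE = -15.0
DEFAULT_E_REPULSIVE = 10.0
DEFAULT_P_CUT = 1e-3
DEFAULT_MIN_COVERAGE = 0.5
DEFAULT_MIN_TM = 0.4


@dataclasses.dataclass
class ComplexTemplate:
    """A two-chain template with its interface contact list."""

    chainA: Structure
    chainB: Structure
    interface_pairs: list[tuple[int, int]] = dataclasses.field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.interface_pairs is None:
            self.interface_pairs = template_interface_pairs(self.chainA, self.chainB)

    @property
    def interface_residues_a(self) -> list[int]:
        return sorted({i for i, _ in self.interface_pairs})

    @property
    def interface_residues_b(self) -> list[int]:
        return sorted({j for _, j in self.interface_pairs})


def _merge(a: Structure, b: Structure) -> Structure:
    merged = a.copy()
    for c in b.copy().chains:
        merged.chains.append(c)
    return merged


def template_interface_pairs(chainA: Structure, chainB: Structure
                             ) -> list[tuple[int, int]]:
    """Inter-chain residue contacts (shared C-beta <= 8 A definition).

    Returned as (index-in-A, index-in-B) flat residue index pairs.
    """
    na = chainA.n_residues
    merged = _merge(chainA, chainB)
    pairs = []
    chain_idx = merged.chain_index()
    n_chains_a = len(chainA.chains)
    for i, j in contact_pairs(merged):
        ca_side = chain_idx[i] < n_chains_a
        cb_side = chain_idx[j] < n_chains_a
        if ca_side != cb_side:
            a_idx, b_idx = (i, j - na) if ca_side else (j, i - na)
            pairs.append((int(a_idx), int(b_idx)))
    return sorted(pairs)


@dataclasses.dataclass
class PutativeComplex:
    """A superposition-assembled dimer with its scores."""

    chainA: Structure                 # monomer A placed in the template frame
    chainB: Structure
    template: ComplexTemplate
    alignA: AlignmentResult
    alignB: AlignmentResult
    coverageA: float
    coverageB: float
    clash_count: int
    e_pp: float | None = None
    is_score: float | None = None
    is_p_value: float | None = None
    label: str = ""


@dataclasses.dataclass
class Rejection:
    """Typed non-acceptance outcome of template-based assembly."""

    reason: str
    tmA: float
    tmB: float
    coverageA: float
    coverageB: float


def _coverage(align: AlignmentResult, interface_residues: Sequence[int]) -> float:
    if not interface_residues:
        return 0.0
    mapped_b = {b for _, b in align.mapping}
    return sum(1 for r in interface_residues if r in mapped_b) / len(interface_residues)


def _inter_chain_clashes(a: Structure, b: Structure,
                         cutoff: float = CLASH_DISTANCE) -> int:
    ta = cKDTree(a.ca_coords())
    return int(sum(len(lst) for lst in ta.query_ball_point(b.ca_coords(), cutoff)))


def assemble(monA: Structure, monB: Structure, template: ComplexTemplate,
             min_coverage: float = DEFAULT_MIN_COVERAGE,
             min_tm: float = DEFAULT_MIN_TM,
             require_both_chains: bool = True,
             alignA: AlignmentResult | None = None,
             alignB: AlignmentResult | None = None
             ) -> PutativeComplex | Rejection:
    """Superpose two monomers onto a dimer template's chains.

    Monomer A is structurally aligned to chain A, monomer B to chain B;
    the putative complex applies both alignment transforms.  Rejected
    (as a typed outcome) when either alignment's TM-score is below
    ``min_tm`` or interface coverage does not exceed ``min_coverage``
    (both chains by default; either chain with
    ``require_both_chains=False``).  Precomputed alignments may be passed
    to amortise large all-against-all screens.
    """
    if monA.n_residues < 20 or monB.n_residues < 20:
        raise ValueError("monomers must have >= 20 residues")
    if alignA is None:
        alignA = structural_align(monA, template.chainA)
    if alignB is None:
        alignB = structural_align(monB, template.chainB)
    covA = _coverage(alignA, template.interface_residues_a)
    covB = _coverage(alignB, template.interface_residues_b)
    tm_ok = alignA.tm >= min_tm and alignB.tm >= min_tm
    if require_both_chains:
        cov_ok = covA > min_coverage and covB > min_coverage
    else:
        cov_ok = covA > min_coverage or covB > min_coverage
    if not (tm_ok and cov_ok):
        reason = "tm" if not tm_ok else "coverage"
        return Rejection(reason, alignA.tm, alignB.tm, covA, covB)
    placedA = monA.transformed(alignA.rotation, alignA.translation)
    placedB = monB.transformed(alignB.rotation, alignB.translation)
    placedA.chains[0].chain_id = "A"
    placedB.chains[0].chain_id = "B"
    clashes = _inter_chain_clashes(placedA, placedB)
    return PutativeComplex(placedA, placedB, template, alignA, alignB,
                           covA, covB, clashes,
                           label=f"{monA.label}|{monB.label}")


def interaction_energy(c: PutativeComplex) -> float:
    """Inter-chain contact energy E_PP plus the clash penalty."""
    pairs = template_interface_pairs(c.chainA, c.chainB)
    namesA = c.chainA.residue_names()
    namesB = c.chainB.residue_names()
    e = sum(chem.contact_energy(namesA[i], namesB[j]) for i, j in pairs)
    e += CLASH_PENALTY * c.clash_count
    c.e_pp = float(e)
    return c.e_pp


def interface_similarity(c: PutativeComplex, template: ComplexTemplate | None = None,
                         calibrator: TailCalibrator | None = None
                         ) -> tuple[float, float | None]:
    """IS-like score against the source template, with optional p-value.

    ``score = (fraction of template interface contacts reproduced)
    x 1/(1 + (interface RMSD / 2 A)^2)``; the interface RMSD is taken over
    the aligned template interface residues after assembly (the assembled
    complex already lives in the template frame).
    """
    template = template or c.template
    if not template.interface_pairs:
        raise ValueError("template interface is empty")
    mapA = {b: a for a, b in c.alignA.mapping}   # template residue -> monomer residue
    mapB = {b: a for a, b in c.alignB.mapping}
    ca_a = c.chainA.ca_coords()
    ca_b = c.chainB.ca_coords()
    t_ca_a = template.chainA.ca_coords()
    t_ca_b = template.chainB.ca_coords()
    inter_a = c.chainA.interaction_coords()
    inter_b = c.chainB.interaction_coords()
    tree_b = cKDTree(inter_b)
    reproduced = 0
    sq = []
    for ta, tb in template.interface_pairs:
        ma = mapA.get(ta)
        mb = mapB.get(tb)
        if ma is None or mb is None:
            continue
        if np.linalg.norm(inter_a[ma] - inter_b[mb]) <= 8.0:
            reproduced += 1
    for ta in template.interface_residues_a:
        ma = mapA.get(ta)
        if ma is not None:
            sq.append(np.sum((ca_a[ma] - t_ca_a[ta]) ** 2))
    for tb in template.interface_residues_b:
        mb = mapB.get(tb)
        if mb is not None:
            sq.append(np.sum((ca_b[mb] - t_ca_b[tb]) ** 2))
    frac = reproduced / len(template.interface_pairs)
    irmsd = float(np.sqrt(np.mean(sq))) if sq else np.inf
    score = frac / (1.0 + (irmsd / 2.0) ** 2) if np.isfinite(irmsd) else 0.0
    c.is_score = float(score)
    p = None
    if calibrator is not None:
        p = float(calibrator.pvalue(score))
        c.is_p_value = p
    return c.is_score, p


# ---------------------------------------------------------------------------
# binding propensity
# ---------------------------------------------------------------------------

def surface_residue_indices(s: Structure, burial_quantile: float = 0.5) -> list[int]:
    """Residues in the less-buried half by contact number (surface proxy)."""
    cn = contact_numbers(s)
    cut = np.quantile(cn, burial_quantile)
    return [int(i) for i in np.flatnonzero(cn <= cut)]


def composition(names: Sequence[str]) -> dict[str, float]:
    names = list(names)
    if not names:
        raise ValueError("empty residue list")
    return {aa: names.count(aa) / len(names) for aa in chem.AMINO_ACIDS}


def propensity_table(interface_freqs: Mapping[str, float],
                     surface_freqs: Mapping[str, float],
                     pseudocount: float = 0.5e-2) -> dict[str, float]:
    """Per-residue log-odds log(f_interface/f_surface) with pseudocounts."""
    table = {}
    for aa in chem.AMINO_ACIDS:
        fs = surface_freqs.get(aa, 0.0) + pseudocount
        fi = interface_freqs.get(aa, 0.0) + pseudocount
        if fs <= 0:
            raise ValueError(f"zero surface frequency for {aa}")
        table[aa] = float(np.log(fi / fs))
    return table


def estimate_propensity_table(templates: Sequence[ComplexTemplate]) -> dict[str, float]:
    """Log-odds table estimated from a template library's interfaces."""
    interface_names: list[str] = []
    surface_names: list[str] = []
    for t in templates:
        for s, iface in ((t.chainA, t.interface_residues_a),
                         (t.chainB, t.interface_residues_b)):
            names = s.residue_names()
            interface_names.extend(names[i] for i in iface)
            iface_set = set(iface)
            surface_names.extend(names[i] for i in surface_residue_indices(s)
                                 if i not in iface_set)
    if not interface_names or not surface_names:
        raise ValueError("library provides no interface/surface residues")
    return propensity_table(composition(interface_names), composition(surface_names))


@dataclasses.dataclass
class PropensityScore:
    value: float


def binding_propensity(interface_residues: Sequence[str],
                       log_odds: Mapping[str, float]) -> PropensityScore:
    """Mean interface log-odds; > 0 implies favourable binding."""
    if not interface_residues:
        raise ValueError("empty interface")
    vals = [log_odds[aa] for aa in interface_residues]
    return PropensityScore(float(np.mean(vals)))


def complex_interface_names(c: PutativeComplex) -> list[str]:
    """Residue identities at the assembled complex's own interface."""
    pairs = template_interface_pairs(c.chainA, c.chainB)
    namesA = c.chainA.residue_names()
    namesB = c.chainB.residue_names()
    out = [namesA[i] for i in sorted({i for i, _ in pairs})]
    out += [namesB[j] for j in sorted({j for _, j in pairs})]
    return out


# ---------------------------------------------------------------------------
# classification and density
# ---------------------------------------------------------------------------

def classify_and_density(complexes: Sequence[PutativeComplex],
                         e_cut: float = DEFAULT_E_ATTRACTIVE,
                         p_cut: float = DEFAULT_P_CUT,
                         e_repulsive: float = DEFAULT_E_REPULSIVE,
                         bins: int = 20
                         ) -> tuple[list[PutativeComplex], list[PutativeComplex],
                                    tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Split into attractive / repulsive sets and bin the (E_PP, log10 p) plane.

    Attractive: E_PP < ``e_cut`` and IS p-value < ``p_cut``; repulsive:
    E_PP > ``e_repulsive``.  The histogram counts sum to the input size.
    """
    attractive = [c for c in complexes
                  if c.e_pp is not None and c.is_p_value is not None
                  and c.e_pp < e_cut and c.is_p_value < p_cut]
    repulsive = [c for c in complexes if c.e_pp is not None and c.e_pp > e_repulsive]
    if complexes:
        e = np.array([c.e_pp if c.e_pp is not None else 0.0 for c in complexes])
        logp = np.array([np.log10(max(c.is_p_value, 1e-12))
                         if c.is_p_value is not None else 0.0 for c in complexes])
        hist, xe, ye = np.histogram2d(e, logp, bins=bins)
    else:
        hist, xe, ye = np.zeros((0, 0)), np.zeros(0), np.zeros(0)
    return attractive, repulsive, (hist, xe, ye)


def shuffled_pair_background(monomers: Sequence[Structure],
                             templates: Sequence[ComplexTemplate],
                             n_scores: int, seed: int = 0,
                             min_coverage: float = 0.0,
                             min_tm: float = 0.0) -> np.ndarray:
    """IS-like scores of randomly paired monomers on random templates.

    The shuffled-pairing null used to calibrate IS p-values: assemble
    random monomer pairs on random templates with no acceptance filter
    and record the interface-similarity scores.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    cache: dict[tuple[int, int, str], AlignmentResult] = {}

    def _align(m_idx: int, t_idx: int, side: str) -> AlignmentResult:
        key = (m_idx, t_idx, side)
        if key not in cache:
            chain = templates[t_idx].chainA if side == "A" else templates[t_idx].chainB
            cache[key] = structural_align(monomers[m_idx], chain)
        return cache[key]

    out = []
    guard = 0
    while len(out) < n_scores and guard < 50 * n_scores:
        guard += 1
        i, j = rng.choice(len(monomers), size=2, replace=False)
        t_idx = int(rng.integers(len(templates)))
        res = assemble(monomers[int(i)], monomers[int(j)], templates[t_idx],
                       min_coverage=min_coverage, min_tm=min_tm,
                       alignA=_align(int(i), t_idx, "A"),
                       alignB=_align(int(j), t_idx, "B"))
        if isinstance(res, Rejection):
            continue
        score, _ = interface_similarity(res)
        out.append(score)
    if len(out) < n_scores:
        raise RuntimeError("could not collect enough background scores")
    return np.asarray(out)
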