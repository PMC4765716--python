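"""Fingerprint-based virtual screening and its survey statistics.

Ligands are bitstring fingerprints compared with the Tanimoto
coefficient TC = |a AND b| / |a OR b|.  The screening scorer is a
template-transfer proxy: a query ligand scores against a target protein
as the best combination of (confidence that one of the target's pockets
matches a template pocket) and (chemical similarity of the query to a
ligand known to bind that template pocket),

    score = max over pocket matches of (1 - p_value) * max TC(query, template ligand),

which is monotone in every TC and in every pocket-match confidence.  On
top of the scorer sit the survey statistics: leader clustering at a TC
cutoff, top-fraction enrichment factors, per-molecule / per-protein
binding-count summaries, and the pathway enrichment factor

    E_p = (mean predicted targets per pathway molecule)
          / (n_proteins x per-ligand call rate),

which equals 1 in expectation under uniform random calls.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from foldfunc.generate import ToyLigandUniverse


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient of two equal-length bitsets."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint lengths differ")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("Tanimoto undefined for two empty fingerprints")
    return float(np.count_nonzero(a & b) / union)


def leader_cluster(fingerprints: Sequence[np.ndarray],
                   tc_cutoff: float = 0.7) -> list[int]:
    """Greedy order-of-input leader clustering; returns leader indices.

    Every ligand has TC >= cutoff to its leader; leaders are pairwise
    below the cutoff.
    """
    if not (0.0 < tc_cutoff <= 1.0):
        raise ValueError("tc_cutoff must be in (0, 1]")
    if not len(fingerprints):
        raise ValueError("empty ligand list")
    leaders: list[int] = []
    for i, fp in enumerate(fingerprints):
        if not any(tanimoto(fp, fingerprints[l]) >= tc_cutoff for l in leaders):
            leaders.append(i)
    return leaders


@dataclasses.dataclass
class PocketMatchEvidence:
    """One template-pocket match usable for ligand transfer."""

    p_value: float
    template_ligands: list[np.ndarray]


def score_ligand(pocket_matches: Sequence[PocketMatchEvidence],
                 query: np.ndarray) -> float | None:
    """Template-transfer screening score in [0, 1]; None without evidence."""
    usable = [m for m in pocket_matches if m.template_ligands]
    if not usable:
        return None
    best = 0.0
    for m in usable:
        conf = 1.0 - m.p_value
        tc = max(tanimoto(query, fp) for fp in m.template_ligands)
        best = max(best, conf * tc)
    return float(best)


def enrichment_factor_top(scores: np.ndarray, is_active: np.ndarray,
                          top_frac: float = 0.01) -> float:
    """EF of the top-ranked fraction: (active share in top) / top_frac.

    Ties are broken by input order (stable sort on descending score).
    EF is 1 in expectation under a random ranking and at most 1/top_frac.
    """
    scores = np.asarray(scores, dtype=float)
    active = np.asarray(is_active, dtype=bool)
    n = scores.size
    if n == 0 or active.sum() == 0:
        raise ValueError("need at least one active ligand")
    n_top = max(1, int(np.floor(top_frac * n)))
    order = np.argsort(-scores, kind="stable")
    top = order[:n_top]
    return float((active[top].sum() / active.sum()) / (n_top / n))


@dataclasses.dataclass
class PathwayEnrichment:
    """Observed vs expected binding-target counts for one pathway."""

    pathway_id: str
    observed_targets: float    # mean predicted binders per pathway molecule
    expected_random: float     # n_proteins x call_rate
    e_p: float
    n_ligands: int


def pathway_enrichment(predictions: Mapping[str, set[str]],
                       pathway_ligands: Sequence[str], pathway_id: str,
                       n_proteins: int, call_rate: float) -> PathwayEnrichment:
    """Pathway enrichment factor E_p = observed / expected mean target count.

    ``predictions`` maps protein id -> set of ligand ids called bound;
    ``call_rate`` is the per-ligand mean call probability of the screen,
    so the random expectation per molecule is ``n_proteins * call_rate``.
    """
    if not pathway_ligands:
        raise ValueError("empty pathway")
    expected = n_proteins * call_rate
    if expected <= 0:
        raise ValueError("expected_random must be positive")
    counts = []
    for lig in pathway_ligands:
        counts.append(sum(1 for ligs in predictions.values() if lig in ligs))
    observed = float(np.mean(counts))
    return PathwayEnrichment(pathway_id, observed, float(expected),
                             observed / expected, len(pathway_ligands))


def binding_statistics(predictions: Mapping[str, set[str]],
                       ligand_ids: Sequence[str]
                       ) -> tuple[float, float, float]:
    """(median targets per molecule, fraction with >= 1 target,
    median molecules per protein)."""
    if not ligand_ids:
        return 0.0, 0.0, 0.0
    per_ligand = np.array([
        sum(1 for ligs in predictions.values() if lig in ligs)
        for lig in ligand_ids])
    per_protein = np.array([len(ligs) for ligs in predictions.values()]) \
        if predictions else np.zeros(0)
    frac = float(np.mean(per_ligand >= 1))
    med_l = float(np.median(per_ligand))
    med_p = float(np.median(per_protein)) if per_protein.size else 0.0
    return med_l, frac, med_p


def simulate_screen(universe: ToyLigandUniverse, call_rate: float,
                    seed: int = 0) -> dict[str, set[str]]:
    """Stochastic binding calls over the toy universe.

    Each (protein, ligand) pair is called bound with probability
    ``call_rate`` times the pair's planted affinity multiplier (capped at
    1); with no planted preferences this is the uniform null.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    out: dict[str, set[str]] = {}
    lig_ids = sorted(universe.fingerprints)
    for prot in universe.protein_ids:
        called = set()
        for lig in lig_ids:
            p = call_rate * universe.planted_preferences.get((prot, lig), 1.0)
            if rng.random() < min(p, 1.0):
                called.add(lig)
        out[prot] = called
    return out


def call_threshold(background_scores: np.ndarray, top_frac: float = 0.01) -> float:
    """Score cutoff at the (1 - top_frac) quantile of a background screen."""
    bg = np.asarray(background_scores, dtype=float)
    if bg.size == 0:
        raise ValueError("empty background")
    return float(np.quantile(bg, 1.0 - top_frac))
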