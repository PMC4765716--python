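# Methods

This note records the models behind each pipeline stage, the parameters
that matter, what the synthetic generators do and do not emulate, and the
design choices made where the design was genuinely open.

## Reduced structural representation

Proteins are chains of residues carrying a 3-letter identity, a C-alpha
coordinate and a pseudo-C-beta placed 1.53 Å along a tetrahedral-like
direction built from the local C-alpha trace (glycine has none; every
operation falls back to C-alpha for it).  The shared contact definition is
C-beta–C-beta ≤ 8 Å (C-alpha for glycine) with sequence separation ≥ 3
within a chain; interfaces, energies and burial all use it, so the stages
are mutually consistent.  Coordinates are Å, residue numbers 1-based,
intervals closed.  PDB I/O goes through gemmi; insertion codes and
duplicate atoms are rejected rather than silently merged.

## Compact backbone generation

Backbones of 40–250 residues are built in three phases:

1. **Fragment assembly** — ideal helix (1.5 Å rise, 100° twist, radius
   chosen so consecutive C-alpha distances are exactly 3.8 Å), strand
   (3.3 Å rise, alternating 0.94 Å offset) and random-loop fragments,
   concatenated with random junction orientations.  The default mix is
   45% helix / 25% strand / 30% loop residues, a typical single-domain
   secondary-structure content.
2. **Metropolis compaction** — pivot and crankshaft moves at loop/junction
   positions against a soft energy penalising radius of gyration above
   0.95 of the bound and non-adjacent pairs closer than the
   self-avoidance distance, under a geometric temperature schedule
   (2.0 → 0.03, 4000 steps by default).
3. **Constraint projection** — Jacobi-style sweeps that alternately
   rescale toward the Rg bound, push clashing pairs apart, and restore
   bond lengths, until every hard constraint holds with margin.

The emitted structure satisfies, exactly: consecutive C-alpha distances
3.8 ± 0.1 Å; all non-adjacent pairs ≥ 4.0 Å; Rg ≤ 2.5·N^⅓ Å.  A seed
that cannot satisfy them within 10 restart attempts raises a generation
error — the library never contains a silently loose structure.  The
projection stage is this package's own addition to the prescribed
assembly + compaction scheme; it is what makes the hard-constraint
guarantee hold on every seed rather than most of them.

What the generator does *not* emulate: real secondary-structure packing
topologies, side chains beyond C-beta, or any folding physics.  Tests
passing on these structures show that the *analyses* behave correctly on
compact self-avoiding chains, not that the chains are native-like.

## Stability-proxy sequence design

Sequences are selected by Metropolis swap moves (identity exchanges at
fixed composition) minimising a packaged 20×20 contact potential
`e(a,b) = −h(a)h(b) + 0.4·q(a)q(b)` with `h` the Kyte–Doolittle
hydropathy rescaled to [0,1] and `q` the formal charge.  The contact
graph is fixed at the input backbone, so swaps never change it and the
recorded best energy can only improve on the initial random sequence.
The potential's absolute scale is arbitrary; every threshold quoted on
summed energies is therefore configuration, and a percentile-calibration
helper maps thresholds to background distributions.  The default
composition is an average globular-protein composition.  The designed
sequences reproduce the hydrophobic-in / polar-out organisation
(verified by contact-number burial ranking in the tests), which is the
only property downstream stages rely on.

For the frozen-catalytic-residue protocol, planted positions are masked
from swap moves, so every designed sequence keeps the catalytic
identities while the rest of the sequence re-equilibrates.

## Pocket detection and comparison

Detection is a protein–solvent–protein (PSP) grid scan: a 1.0 Å grid in
a canonical frame (centroid origin, principal axes with third-moment
sign fixing, which makes pocket counts and volumes invariant under rigid
transforms); grid points within 2.8 Å of any atom are protein; an empty
point is pocket-like when ≥ 5 of 7 scan directions (3 axes + 4 body
diagonals) are blocked by protein within 10 Å on both sides; connected
components of ≥ 30 points are pockets.  The 2.8 Å occupancy radius is
the one genuinely tuned constant: small enough that a planted cavity of
radius ≥ 4 Å survives, large enough that the interstitial voids of a
packed C-alpha/C-beta model do not percolate into spurious pockets.
Lining residues sit within 5 Å of a grid point.

Pockets are compared by maximising, over one-to-one residue
correspondences,

    score = (aligned fraction) × 1/(1 + (RMSD/2 Å)²) × (class agreement),

with six chemical classes (hydrophobic, aromatic, polar, charged±,
Gly/Pro).  Tiny pockets (≤ 6 residues each) are solved exactly by
enumeration; larger ones by a seeded ICP: principal-axes and random
rotation seeds, Hungarian assignment alternating distance-only and
class-biased costs, and a closed-form prefix-RMSD that scores every
top-k sub-correspondence per sweep.  The search is symmetric by
construction (both directions, maximum taken).  Self-comparison scores
1; the heuristic is exact on small pockets (tested against brute force)
but is, like any ICP, not guaranteed globally optimal on large ones.

**p-values.**  Scores are calibrated on unrelated-pair backgrounds with a
rank-based estimator `p = (1 + #{bg > s})/(n+1)`, with a fitted Gumbel
right tail used only beyond the observed background maximum (clamped at
the rank bound).  A pure extreme-value fit was rejected: a misspecified
parametric family fails finite-sample uniformity, while the rank
estimator makes held-out null p-values uniform by construction.  The
interface-similarity null has a point mass at zero (assemblies that
reproduce no template contact); p-values are conservative at that atom,
and calibration diagnostics use the randomized probability integral
transform, the standard device for discrete nulls.

## Active-site matching

A template is an unordered constellation of 3–5 residues (identity +
C-alpha/C-beta).  Matching enumerates identity-consistent assignments of
template residues to target residues, pruned by pairwise C-alpha
distance compatibility at 1.5 Å tolerance — a bound loose enough, by the
triangle inequality, that no true sub-1 Å hit can be pruned (verified
against exhaustive enumeration) — and scores survivors by Kabsch RMSD
over C-alpha + C-beta.  A hit requires full coverage, full identity and
RMSD below the cutoff (0.5 / 0.75 / 1.0 Å grids).  Scans discard hits
whose source structure aligns to the target at TM-score ≥ 0.4, so only
convergent (not homologous) geometry counts.  Class counts deduplicate
EC numbers at the requested digit depth and cumulative curves report the
fraction of targets hitting ≥ k classes.

The synthetic CSA-like library extracts mutually proximate residue sets
(pairwise 4.5–11 Å) from generated structures, overwrites their
identities from a catalytic-residue pool, and attaches random EC
numbers.  Site planting grafts a constellation onto anchor residues
chosen for distance-matrix similarity to the template (anchors ≥ 3 apart
in sequence, so no backbone bond or sandwiched residue is frozen), with
Gaussian coordinate jitter, and repairs the surrounding chain by
constraint projection with frozen anchors.

## Structural alignment

A TM-align-flavoured iterative aligner: seeds from gapless offset
alignments (plus, in thorough mode, every 3-residue fragment-pair
superposition), then alternating superposition (Kabsch) and dynamic
programming on the TM-score similarity matrix (gap −0.6, free terminal
gaps, ties toward lower indices), to convergence or 20 rounds.  The
result is the best over all seeds and iterations, so it never falls
below the best rigid seed.  TM-scores are normalised by the *target*
(second) structure's length with d0 clamped at 0.5 Å for short chains.
Kabsch superposition itself is scipy's `Rotation.align_vectors`, with
RMSD recomputed from residuals (the reported rssd loses precision near
zero); an independent quaternion-eigenvalue oracle checks it in the
tests.

## Ligand screen

Fingerprints are random bitstrings (64 bits, density 0.15 by default);
chemistry enters only through Tanimoto similarity, which is all the
screening statistics need.  The scorer transfers ligands across pocket
matches: `score = max over matched template pockets of (1 − p) × max
TC(query, template ligand)` — monotone in both factors, 1 for a known
binder of a self-matched pocket.  Binding calls use a top-1%
background-quantile threshold.  E_p is the ratio of the observed mean
number of predicted protein targets per pathway molecule to the
random-call expectation `n_proteins × call rate`; it is 1 in expectation
under uniform calls (simulation-tested) and recovers a planted 10×
pathway preference.  The printed form of the enrichment definition in
the source literature is ambiguous; this observed-over-expected reading
is the one implemented, and a per-protein normalisation would change
only the scale, not the null-centring property the tests verify.

## Complex assembly (protein–protein and protein–DNA)

Dimer templates are built by rigid docking of two designed monomers:
random orientations slide into contact, candidates need ≥ 10 inter-chain
contacts and no C-alpha pair below 3.5 Å, and the lowest-contact-energy
candidate among the valid trials is kept — native-like templates present
energetically favourable, hydrophobic-enriched faces, which is what the
propensity statistics measure.  Assembly aligns each monomer to its
template chain and applies the transforms; acceptance needs TM ≥ the
configured threshold on both chains and interface coverage > 0.5 (both
chains by default; a config switch relaxes to either).  The desk-scale
default TM threshold is 0.2: with tens rather than millions of candidate
pairs, the survey would otherwise accept nothing, and the threshold is
explicitly a scale-dependent config value.  `E_PP` sums the contact
potential over inter-chain contacts plus 10.0 per clash.  Interface
similarity is the fraction of template interface contacts reproduced,
damped by interface RMSD, with calibrated p-values.  Binding propensity
is the mean per-residue log-odds `log(f_interface/f_surface)` with
frequencies estimated from the template library (surface = less-buried
half by contact number; 0.005 pseudocounts).  A literal per-interface
log-odds-of-itself reading would give a KL divergence, which can never
be negative and so cannot mark repulsive interfaces; the library-table
form is used instead.

The DNA channel mirrors this with an ideal B-form duplex (3.4 Å rise,
36° twist, two-site nucleotides: phosphate at 8.9 Å and base centroid at
4.0 Å from the axis, antiparallel complementary strands).  Base identity
is carried but unused by the energy — binding is modelled as
sequence-nonspecific charge complementarity, with Arg/Lys–phosphate
attraction and Asp/Glu–phosphate repulsion in a 20×2 potential.  The
interfacial TM-score is the TM-score restricted to the template
protein's DNA-interface residues, normalised by interface size.
Classification thresholds (E_DP < −10, iTM ≥ 0.4, E_PP < −15) are kept
as config defaults for continuity but are scale-dependent on this
potential; percentile calibration against backgrounds is the supported
way to place them.

## Pipeline, determinism and problem sizes

One global seed is expanded into per-stage seeds via numpy
`SeedSequence` spawning; every generator draws from an explicit
`np.random.Generator`, never global state, so a configuration reproduces
its outputs bit for bit (manifest SHA-256 hashes are compared in the
tests).  The default survey — 50 structures of 48–80 residues, 6 site
templates, a 300-ligand / 10-pathway universe, 5 dimer and 5 DNA
templates, 60 monomer pairs — runs in a few minutes on one core; these
sizes were chosen as the smallest library on which every channel has
enough statistics to calibrate its p-values (≥ 100 background scores per
channel).  Tests use smaller replicas of the same generators.

## Benchmark constructions used in the tests

* *Planted cavities* are carved from jittered-lattice pseudo-proteins
  (cavity radius 5 Å, a narrow mouth channel); dense lattice balls serve
  as the no-enclosure negative control.  Real pockets are packing
  defects, not carved spheres; the construction tests recovery, not
  realism.
* *Energy-ranking AUC* compares template-derived assemblies (template
  chains with 0.25 Å coordinate jitter) against randomly re-docked
  chains (rotated in place, clash-prone).  Separation is expected
  because re-docking destroys favourable contacts and creates clashes.
* *Propensity contrast* holds geometry fixed and randomises sequence, so
  interface composition alone drives the energy classes; clash-driven
  negatives would instead expose buried (hydrophobic) residues and
  invert the comparison, which is a representation artifact rather than
  a claim about binding.

## Known limitations

* The reduced representation has no real side chains; chemical classes
  and hydropathy stand in for chemistry everywhere.
* The pocket comparison and structural alignment are heuristic
  optimisers; they are exact only where the tests prove them so (tiny
  pockets, small-structure fragment seeding).
* The energy scales are internal; absolute values are not comparable to
  physical free energies or to thresholds quoted for other potentials.
* The survey sizes are desk-scale; frequencies of rare events (e.g.
  attractive complexes) have large relative error at these sizes, and
  the pipeline reports counts, not extrapolations.
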