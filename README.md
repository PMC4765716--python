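# foldfunc

How much native-like biochemistry does a protein get *for free*, simply by
being compact and stable?  `foldfunc` is a desk-scale pipeline for asking
that question with synthetic data: it generates libraries of compact
single-domain protein structures whose sequences are selected only for a
stability proxy — never for function — and then surveys how often those
structures carry the structural signatures of biochemical function:

* **ligand-binding pockets**, detected with a geometry-based
  protein–solvent–protein grid scan, compared with a pocket-similarity
  (PS-like) score, calibrated to p-values and clustered into
  representatives;
* **enzyme-like active sites**: 3–5-residue catalytic constellations
  matched by identity-constrained geometric search (a *hit* requires
  100% residue identity and superposition RMSD below a cutoff, with a
  TM-score < 0.4 filter so only globally unrelated folds count);
* **metabolite binding**: a fingerprint/Tanimoto virtual screen with
  top-1% enrichment factors and a pathway enrichment factor
  `E_p = (mean predicted targets per pathway molecule) / (n_proteins × call rate)`;
* **protein–protein and protein–DNA complexes**: monomers superposed onto
  native-like dimer or B-DNA templates (kept when aligned to > 50% of the
  template interface), scored with inter-chain contact energies `E_PP` /
  `E_DP`, interface-similarity and interfacial-TM scores, and
  composition log-odds binding propensities.

All reference data — structures, catalytic-site templates, dimer and DNA
templates, the ligand/pathway universe — are generated synthetically with
seeded, fully deterministic generators, so every experiment runs on a
laptop with a known ground truth.  It is aimed at computational structural
biologists who want a transparent, testable sandbox for "intrinsic
function" analyses rather than a production annotation tool.

## Worked example

```python
from foldfunc import (GeneratorConfig, generate_compact_backbone,
                      design_stable_sequence, detect_pockets)
from foldfunc.generate import make_dimer_template
from foldfunc.complexes import assemble, interaction_energy, interface_similarity
from foldfunc.structure import radius_of_gyration

cfg = GeneratorConfig(n_residues=80, seed=42)
backbone = generate_compact_backbone(cfg)
design = design_stable_sequence(backbone, mc_steps=8000, seed=42)
s = design.structure
print(f"backbone: {s.n_residues} residues, Rg = {radius_of_gyration(s.ca_coords()):.2f} A")
print(f"design energy: {design.initial_energy:.1f} -> {design.final_energy:.1f}")

pockets = detect_pockets(s)
print(f"pockets: {len(pockets)}; largest = {pockets[0].volume:.0f} A^3")

template = make_dimer_template(7, 8, min_contacts=10, n_residues=48)
complex_ = assemble(template.chainA, template.chainB, template)
e = interaction_energy(complex_)
is_score, _ = interface_similarity(complex_)
print(f"self-assembly E_PP = {e:.2f}, IS = {is_score:.3f}")
```

prints

```
backbone: 80 residues, Rg = 10.35 A
design energy: -75.4 -> -154.4
pockets: 1; largest = 484 A^3
self-assembly E_PP = -16.07, IS = 1.000
```

The 80-residue backbone satisfies its compactness bound
(Rg ≤ 2.5·N^⅓ = 10.77 Å); Metropolis sequence selection halves the
contact energy, burying hydrophobic residues; the packing defects of the
compact fold already form a ~480 Å³ pocket; and re-assembling a dimer
template from its own chains reproduces it exactly (interface similarity
1.0) at a favourable interaction energy.

## Command line

The full survey runs end to end from a single seed:

```bash
foldfunc run --seed 7 --outdir runs/demo            # all stages
foldfunc pockets --config cfg.yaml --seed 7         # one stage + deps
```

Stages (`generate | pockets | sites | screen | complexes | dna | report`)
write TSV/JSON artifacts plus a manifest with a SHA-256 hash per output;
identical configurations reproduce identical hashes bit for bit.

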