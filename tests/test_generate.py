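"""Synthetic-structure generators: geometry, design, planting, templates."""

import numpy as np
import pytest

from foldfunc import chem
from foldfunc.generate import (
    GenerationError,
    GeneratorConfig,
    PlantSpec,
    backbone_violations,
    choose_plant_anchors,
    design_stable_sequence,
    generate_compact_backbone,
    make_bdna_complex_template,
    make_dimer_template,
    make_ligand_pathway_universe,
    plant_site,
)
from foldfunc.structure import contact_numbers, kabsch_superpose, radius_of_gyration


# ---------------------------------------------------------------------------
# compact backbones
# ---------------------------------------------------------------------------

class TestBackbone:
    def test_bond_lengths(self):
        s = generate_compact_backbone(GeneratorConfig(n_residues=100, seed=1))
        bonds = np.linalg.norm(np.diff(s.ca_coords(), axis=0), axis=1)
        assert np.all(np.abs(bonds - 3.8) <= 0.1)

    def test_seed_determinism(self):
        cfg = dict(n_residues=40, seed=2)
        a = generate_compact_backbone(GeneratorConfig(**cfg))
        b = generate_compact_backbone(GeneratorConfig(**cfg))
        assert np.array_equal(a.ca_coords(), b.ca_coords())

    @pytest.mark.parametrize("seed", range(12))
    def test_geometry_constraints_across_seeds(self, seed):
        """Every emitted backbone satisfies bond, avoidance and Rg bounds."""
        cfg = GeneratorConfig(n_residues=44 + 2 * seed, seed=seed, mc_steps=2500)
        s = generate_compact_backbone(cfg)
        assert backbone_violations(s.ca_coords(), cfg.rg_max,
                                   cfg.min_separation) == []
        assert radius_of_gyration(s.ca_coords()) <= \
            cfg.compactness_coefficient * cfg.n_residues ** (1 / 3)

    def test_impossible_compactness_raises(self):
        cfg = GeneratorConfig(n_residues=100, seed=0,
                              compactness_coefficient=1.0,
                              mc_steps=300, max_attempts=2)
        with pytest.raises(GenerationError):
            generate_compact_backbone(cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_residues=30, seed=0)
        with pytest.raises(ValueError):
            GeneratorConfig(n_residues=300, seed=0)
        with pytest.raises(ValueError):
            GeneratorConfig(n_residues=50, seed=0, fragment_mix=(0.9, 0.4, 0.1))


# ---------------------------------------------------------------------------
# sequence design
# ---------------------------------------------------------------------------

class TestSequenceDesign:
    def test_zero_steps_returns_initial(self, small_library):
        bb = small_library[0]
        a = design_stable_sequence(bb, mc_steps=0, seed=9)
        b = design_stable_sequence(bb, mc_steps=0, seed=9)
        assert a.structure.residue_names() == b.structure.residue_names()
        assert a.initial_energy == a.final_energy

    def test_energy_never_increases(self, small_library):
        for seed in range(4):
            res = design_stable_sequence(small_library[1], mc_steps=4000,
                                         seed=seed)
            assert res.final_energy <= res.initial_energy

    def test_composition_preserved_by_swaps(self, small_library):
        res = design_stable_sequence(small_library[2], mc_steps=3000, seed=3)
        res0 = design_stable_sequence(small_library[2], mc_steps=0, seed=3)
        assert sorted(res.structure.residue_names()) == \
            sorted(res0.structure.residue_names())

    def test_empty_composition_is_error(self, small_library):
        with pytest.raises(ValueError):
            design_stable_sequence(small_library[0], composition={}, seed=0)

    def test_frozen_positions_kept(self, small_library):
        frozen = {0: "HIS", 5: "ASP", 11: "SER"}
        res = design_stable_sequence(small_library[3], mc_steps=2000, seed=1,
                                     frozen=frozen)
        names = res.structure.residue_names()
        assert all(names[i] == aa for i, aa in frozen.items())

    def test_hydrophobic_core_forms(self, small_library):
        """Buried positions end up hydrophobic-enriched in nearly all designs."""
        wins = 0
        trials = 0
        for s_idx in range(4):
            bb = small_library[s_idx]
            for seed in range(5):
                res = design_stable_sequence(bb, mc_steps=4000, seed=seed)
                names = res.structure.residue_names()
                hyd = np.array([n in chem.HYDROPHOBIC_SET for n in names])
                cn = contact_numbers(res.structure)
                k = max(1, len(names) // 4)
                buried = np.argsort(-cn, kind="stable")[:k]
                trials += 1
                wins += hyd[buried].mean() > hyd.mean()
        assert wins / trials >= 0.9


# ---------------------------------------------------------------------------
# site planting
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def site_fixture(small_library):
    from foldfunc.sites import make_site_template_library
    return make_site_template_library(2, seed=5, sizes=(3, 4))


class TestPlantSite:
    def test_zero_jitter_exact_constellation(self, small_library, site_fixture):
        tpl = site_fixture[0]
        s = small_library[4]
        anchors = choose_plant_anchors(s, tpl.ca, seed=1)
        spec = PlantSpec("t", jitter_sd=0.0, anchor_residue_indices=anchors)
        planted = plant_site(s, tpl.residue_names, tpl.ca, tpl.cb, spec, seed=2)
        ca = planted.ca_coords()[list(anchors)]
        _, _, rmsd = kabsch_superpose(tpl.ca, ca)
        assert rmsd <= 1e-6
        names = planted.residue_names()
        assert tuple(names[i] for i in anchors) == tpl.residue_names

    def test_jittered_constellation_rmsd(self, small_library, site_fixture):
        tpl = site_fixture[1]
        s = small_library[5]
        anchors = choose_plant_anchors(s, tpl.ca, seed=3)
        rmsds = []
        for trial in range(25):
            spec = PlantSpec("t", jitter_sd=0.1, anchor_residue_indices=anchors)
            planted = plant_site(s, tpl.residue_names, tpl.ca, tpl.cb, spec,
                                 seed=trial)
            ca = planted.ca_coords()[list(anchors)]
            _, _, rmsd = kabsch_superpose(tpl.ca, ca)
            rmsds.append(rmsd)
            assert rmsd <= 3 * 0.1 + 1e-9
            names = planted.residue_names()
            assert tuple(names[i] for i in anchors) == tpl.residue_names
        assert np.mean(rmsds) <= 0.3

    def test_backbone_repaired_around_plant(self, small_library, site_fixture):
        tpl = site_fixture[0]
        s = small_library[6]
        anchors = choose_plant_anchors(s, tpl.ca, seed=4)
        spec = PlantSpec("t", jitter_sd=0.0, anchor_residue_indices=anchors)
        planted = plant_site(s, tpl.residue_names, tpl.ca, tpl.cb, spec, seed=5)
        bonds = np.linalg.norm(np.diff(planted.ca_coords(), axis=0), axis=1)
        assert np.all(np.abs(bonds - 3.8) <= 0.1)

    def test_anchor_count_mismatch(self, small_library, site_fixture):
        tpl = site_fixture[0]
        spec = PlantSpec("t", anchor_residue_indices=(1, 2))
        with pytest.raises(ValueError):
            plant_site(small_library[0], tpl.residue_names, tpl.ca, tpl.cb,
                       spec, seed=0)


# ---------------------------------------------------------------------------
# dimer templates
# ---------------------------------------------------------------------------

class TestDimerTemplate:
    def test_contacts_and_no_clash(self):
        tpl = make_dimer_template(3, 4, min_contacts=10, n_residues=48)
        assert len(tpl.interface_pairs) >= 10
        ca_a = tpl.chainA.ca_coords()
        ca_b = tpl.chainB.ca_coords()
        d = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=2)
        assert d.min() >= 3.5

    def test_determinism(self):
        a = make_dimer_template(5, 6, min_contacts=8, n_residues=48)
        b = make_dimer_template(5, 6, min_contacts=8, n_residues=48)
        assert np.array_equal(a.chainB.ca_coords(), b.chainB.ca_coords())
        assert a.interface_pairs == b.interface_pairs

    def test_contact_count_equals_brute_force(self):
        tpl = make_dimer_template(7, 8, min_contacts=8, n_residues=48)
        ia = tpl.chainA.interaction_coords()
        ib = tpl.chainB.interaction_coords()
        brute = [(i, j) for i in range(len(ia)) for j in range(len(ib))
                 if np.linalg.norm(ia[i] - ib[j]) <= 8.0]
        assert tpl.interface_pairs == brute

    def test_min_contacts_validation(self):
        with pytest.raises(ValueError):
            make_dimer_template(1, 2, min_contacts=0)


# ---------------------------------------------------------------------------
# B-DNA complex templates
# ---------------------------------------------------------------------------

class TestBdnaTemplate:
    def test_contact_count_matches_brute_force(self, small_library):
        tpl = make_bdna_complex_template(10, small_library[7], seed=2)
        inter = tpl.protein.interaction_coords()
        sites = [("P", tpl.dna.phosphates), ("B", tpl.dna.centroids)]
        brute = sorted(
            (ri, nj, lab)
            for lab, coords in sites
            for ri in range(len(inter))
            for nj in range(len(coords))
            if np.linalg.norm(inter[ri] - coords[nj]) <= 7.0)
        assert tpl.interface_pairs == brute
        assert len(tpl.interface_pairs) >= 5

    def test_n_bp_validation(self, small_library):
        with pytest.raises(ValueError):
            make_bdna_complex_template(3, small_library[0], seed=0)


# ---------------------------------------------------------------------------
# ligand / pathway universe
# ---------------------------------------------------------------------------

class TestLigandUniverse:
    def test_uniform_null_has_no_preferences(self):
        u = make_ligand_pathway_universe(50, 5, planted_fold=1.0, seed=0)
        assert u.planted_preferences == {}

    def test_determinism(self):
        a = make_ligand_pathway_universe(60, 6, planted_fold=5.0, seed=3)
        b = make_ligand_pathway_universe(60, 6, planted_fold=5.0, seed=3)
        assert a.pathways == b.pathways
        assert a.planted_preferences == b.planted_preferences
        assert all(np.array_equal(a.fingerprints[k], b.fingerprints[k])
                   for k in a.fingerprints)

    def test_pathways_partition_a_subset(self):
        u = make_ligand_pathway_universe(80, 8, seed=1)
        seen = [lig for ligs in u.pathways.values() for lig in ligs]
        assert len(seen) == len(set(seen))
        assert all(lig in u.fingerprints for lig in seen)

    def test_fingerprint_density_within_binomial_ci(self):
        p = 0.15
        u = make_ligand_pathway_universe(200, 5, n_bits=64, bit_prob=p, seed=4)
        total_bits = 200 * 64
        ones = sum(int(fp.sum()) for fp in u.fingerprints.values())
        # exact binomial 99% CI around the configured bit probability
        from scipy import stats
        lo, hi = stats.binom.interval(0.99, total_bits, p)
        assert lo <= ones <= hi

    def test_too_many_pathways_is_error(self):
        with pytest.raises(ValueError):
            make_ligand_pathway_universe(5, 10, seed=0)

    def test_planted_fold_validation(self):
        with pytest.raises(ValueError):
            make_ligand_pathway_universe(10, 2, planted_fold=0.5, seed=0)
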