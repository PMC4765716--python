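"""Dimer assembly, interface energies, similarity and propensity scores."""

import numpy as np
import pytest

from foldfunc import chem
from foldfunc.calibration import TailCalibrator
from foldfunc.complexes import (
    ComplexTemplate,
    PutativeComplex,
    Rejection,
    assemble,
    binding_propensity,
    classify_and_density,
    estimate_propensity_table,
    interaction_energy,
    interface_similarity,
    propensity_table,
    shuffled_pair_background,
    template_interface_pairs,
)
from foldfunc.generate import make_dimer_template
from foldfunc.structure import Structure, random_rotation


@pytest.fixture(scope="module")
def template():
    return make_dimer_template(31, 32, min_contacts=10, n_residues=48)


@pytest.fixture(scope="module")
def self_assembled(template):
    res = assemble(template.chainA, template.chainB, template)
    assert not isinstance(res, Rejection)
    return res


def two_residue_chain(names, positions, chain_id="A"):
    return Structure.from_arrays(names, np.asarray(positions, float),
                                 chain_id=chain_id)


class TestAssembly:
    def test_self_assembly_reproduces_template(self, template, self_assembled):
        c = self_assembled
        assert c.coverageA == 1.0 and c.coverageB == 1.0
        assert np.abs(c.chainA.ca_coords() -
                      template.chainA.ca_coords()).max() <= 1e-6
        assert np.abs(c.chainB.ca_coords() -
                      template.chainB.ca_coords()).max() <= 1e-6

    def test_impossible_coverage_rejects_everything(self, template):
        res = assemble(template.chainA, template.chainB, template,
                       min_coverage=1.01)
        assert isinstance(res, Rejection)

    def test_coverage_equals_recount(self, template, small_library):
        res = assemble(small_library[0], small_library[1], template,
                       min_coverage=0.0, min_tm=0.0)
        assert isinstance(res, PutativeComplex)
        mapped_a = {b for _, b in res.alignA.mapping}
        cov_a = sum(1 for r in template.interface_residues_a
                    if r in mapped_a) / len(template.interface_residues_a)
        assert res.coverageA == pytest.approx(cov_a)

    def test_small_monomer_is_error(self, template):
        tiny = two_residue_chain(["ALA"] * 5,
                                 np.cumsum(np.ones((5, 3)), axis=0))
        with pytest.raises(ValueError):
            assemble(tiny, template.chainB, template)


class TestInteractionEnergy:
    def test_zero_without_contacts(self):
        a = two_residue_chain(["ALA", "LEU", "VAL"],
                              [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        b = two_residue_chain(["ALA", "LEU", "VAL"],
                              [[50, 0, 0], [53.8, 0, 0], [57.6, 0, 0]], "B")
        tpl = ComplexTemplate(a, b, interface_pairs=[])
        c = PutativeComplex(a, b, tpl, None, None, 1.0, 1.0, 0)
        assert interaction_energy(c) == 0.0

    def test_manual_two_contact_sum(self):
        # two ILE-ILE contacts across the interface, no clashes
        a = two_residue_chain(["ILE", "ILE", "GLY"],
                              [[0, 0, 0], [6.0, 0, 0], [40, 40, 40]])
        b = two_residue_chain(["ILE", "ILE", "GLY"],
                              [[0, 5.0, 0], [6.0, 5.0, 0], [80, 80, 80]], "B")
        tpl = ComplexTemplate(a, b)
        c = PutativeComplex(a, b, tpl, None, None, 1.0, 1.0, 0)
        e = interaction_energy(c)
        pairs = template_interface_pairs(a, b)
        manual = sum(chem.contact_energy(a.residue_names()[i],
                                         b.residue_names()[j])
                     for i, j in pairs)
        assert e == pytest.approx(manual)
        assert len(pairs) >= 2

    def test_clash_penalty_dominates(self, template):
        # superpose chain B onto chain A: many C-alpha clashes
        clashed = template.chainA.copy()
        clashed.chains[0].chain_id = "B"
        tpl = ComplexTemplate(template.chainA, clashed)
        n_res = template.chainA.n_residues
        c = PutativeComplex(template.chainA, clashed, tpl, None, None,
                            1.0, 1.0, clash_count=n_res)
        assert interaction_energy(c) > 10.0

    def test_rigid_invariance(self, self_assembled):
        rng = np.random.default_rng(4)
        e0 = interaction_energy(self_assembled)
        R = random_rotation(rng)
        t = rng.normal(0, 20, 3)
        moved = PutativeComplex(
            self_assembled.chainA.transformed(R, t),
            self_assembled.chainB.transformed(R, t),
            self_assembled.template, self_assembled.alignA,
            self_assembled.alignB, 1.0, 1.0, self_assembled.clash_count)
        assert interaction_energy(moved) == pytest.approx(e0, abs=1e-9)


class TestInterfaceSimilarity:
    def test_self_assembly_is_one(self, self_assembled):
        score, _ = interface_similarity(self_assembled)
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_redocked_chains_score_zero(self, template):
        rng = np.random.default_rng(5)
        # rotate chain B in place: template contacts destroyed
        R = random_rotation(rng)
        centre = template.chainB.ca_coords().mean(axis=0)
        wrecked = template.chainB.transformed(R, centre - R @ centre +
                                              np.array([60.0, 0, 0]))
        res = assemble(template.chainA, template.chainB, template)
        res.chainB = wrecked
        score, _ = interface_similarity(res)
        assert score <= 0.05

    def test_contact_overlap_recount(self, template, small_library):
        res = assemble(small_library[2], small_library[3], template,
                       min_coverage=0.0, min_tm=0.0)
        assert isinstance(res, PutativeComplex)
        score, _ = interface_similarity(res)
        mapA = {b: a for a, b in res.alignA.mapping}
        mapB = {b: a for a, b in res.alignB.mapping}
        ia = res.chainA.interaction_coords()
        ib = res.chainB.interaction_coords()
        n_rep = 0
        for ta, tb in template.interface_pairs:
            ma, mb = mapA.get(ta), mapB.get(tb)
            if ma is not None and mb is not None and \
                    np.linalg.norm(ia[ma] - ib[mb]) <= 8.0:
                n_rep += 1
        frac = n_rep / len(template.interface_pairs)
        assert score <= frac + 1e-9

    def test_calibrated_pvalue(self, template, small_library):
        bg = shuffled_pair_background(small_library, [template], 120, seed=0)
        cal = TailCalibrator(bg)
        res = assemble(template.chainA, template.chainB, template)
        score, p = interface_similarity(res, calibrator=cal)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert p <= 1 / (len(bg) + 1)


class TestPropensity:
    def test_zero_table_gives_zero(self):
        table = {aa: 0.0 for aa in chem.AMINO_ACIDS}
        assert binding_propensity(["ALA", "TRP"], table).value == 0.0

    def test_mean_of_log_odds(self):
        table = {aa: 0.0 for aa in chem.AMINO_ACIDS}
        table["ILE"] = 0.3
        table["ASP"] = -0.1
        assert binding_propensity(["ILE", "ASP"], table).value == \
            pytest.approx(0.1)

    def test_flat_library_table_is_zero(self):
        freqs = {aa: 1 / 20 for aa in chem.AMINO_ACIDS}
        table = propensity_table(freqs, freqs)
        assert all(abs(v) < 1e-12 for v in table.values())

    def test_zero_surface_frequency_is_error(self):
        freqs = {aa: 1 / 20 for aa in chem.AMINO_ACIDS}
        with pytest.raises(ValueError):
            propensity_table(freqs, {aa: -1e-2 + 0.0 for aa in chem.AMINO_ACIDS})

    def test_empty_interface_is_error(self):
        with pytest.raises(ValueError):
            binding_propensity([], {aa: 0.0 for aa in chem.AMINO_ACIDS})

    def test_library_estimate_covers_all_amino_acids(self, template):
        table = estimate_propensity_table([template])
        assert set(table) == set(chem.AMINO_ACIDS)
        assert all(np.isfinite(v) for v in table.values())


class TestClassification:
    def test_empty_input(self):
        att, rep, (hist, _, _) = classify_and_density([])
        assert att == [] and rep == [] and hist.size == 0

    def test_single_attractive(self, self_assembled):
        c = self_assembled
        c.e_pp = -20.0
        c.is_p_value = 1e-4
        att, rep, (hist, _, _) = classify_and_density([c])
        assert att == [c] and rep == []
        assert hist.sum() == 1

    def test_counts_equal_recount(self, template, small_library):
        rng = np.random.default_rng(6)
        cs = []
        for k in range(12):
            c = assemble(template.chainA, template.chainB, template)
            c.e_pp = float(rng.normal(-10, 10))
            c.is_p_value = float(rng.random())
            cs.append(c)
        att, rep, (hist, _, _) = classify_and_density(cs)
        assert len(att) == sum(1 for c in cs
                               if c.e_pp < -15 and c.is_p_value < 1e-3)
        assert len(rep) == sum(1 for c in cs if c.e_pp > 10)
        assert hist.sum() == len(cs)
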