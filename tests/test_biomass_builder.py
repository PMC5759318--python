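"""Biomass composition arithmetic and reaction assembly."""

import collections

import numpy as np
import pytest

from halogem.biomass_builder import (
    AMINO_ACIDS,
    ENERGY_TERM,
    BiomassComposition,
    CompositionError,
    amino_acid_ratios_from_proteome,
    assemble_biomass_reaction,
    compute_gam,
    dnt_ratios_from_gc,
    nt_ratios_from_rna_mix,
)


class TestComputeGam:
    @pytest.mark.parametrize(
        "base, poly, total",
        [
            (36.94, 23.04, 59.98),  # low salinity
            (36.94, 8.79, 45.73),  # high salinity
            (12.5, 0.0, 12.5),  # additive identity
        ],
    )
    def test_exact_sum(self, base, poly, total):
        assert compute_gam(base, poly) == total

    def test_no_float_drift_in_report(self):
        # the naive float sum 36.94 + 8.79 is 45.730000000000004
        assert repr(compute_gam(36.94, 8.79)) == "45.73"

    def test_negative_rejected(self):
        with pytest.raises(CompositionError):
            compute_gam(-1.0, 5.0)


class TestMonomerRatios:
    @pytest.mark.parametrize(
        "seqs, expected",
        [
            (["GG", "AA"], {"G": 0.5, "A": 0.5}),
            (["MKV"], {"M": 1 / 3, "K": 1 / 3, "V": 1 / 3}),
        ],
    )
    def test_amino_acid_ratios(self, seqs, expected):
        ratios = amino_acid_ratios_from_proteome(seqs)
        for a in AMINO_ACIDS:
            assert ratios[a] == pytest.approx(expected.get(a, 0.0), abs=1e-12)
        assert sum(ratios.values()) == pytest.approx(1.0)

    def test_random_proteome_matches_counting_oracle(self):
        rng = np.random.default_rng(42)
        seqs = [
            "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(5, 40)))
            for _ in range(10)
        ]
        ratios = amino_acid_ratios_from_proteome(seqs)
        counter = collections.Counter("".join(seqs))  # independent letter count
        total = sum(counter.values())
        for a in AMINO_ACIDS:
            assert ratios[a] == pytest.approx(counter[a] / total, abs=1e-12)

    def test_bad_inputs(self):
        with pytest.raises(CompositionError):
            amino_acid_ratios_from_proteome([])
        with pytest.raises(CompositionError, match="sequence 1"):
            amino_acid_ratios_from_proteome(["MKV", "MXV"])

    @pytest.mark.parametrize(
        "gc, dA, dG",
        [(0.5, 0.25, 0.25), (0.0, 0.5, 0.0), (0.6, 0.2, 0.3)],
    )
    def test_dnt_ratios(self, gc, dA, dG):
        r = dnt_ratios_from_gc(gc)
        assert r["dATP"] == r["dTTP"] == pytest.approx(dA)
        assert r["dGTP"] == r["dCTP"] == pytest.approx(dG)

    def test_dnt_out_of_range(self):
        with pytest.raises(CompositionError):
            dnt_ratios_from_gc(1.2)

    def test_rna_mix_normalizes(self):
        uniform = {nt: 0.25 for nt in ("ATP", "CTP", "GTP", "UTP")}
        mix = nt_ratios_from_rna_mix(uniform, uniform, uniform)
        assert sum(mix.values()) == pytest.approx(1.0)
        assert mix["ATP"] == pytest.approx(0.25)


def _composition(protein=0.55, dna=0.05, rna=0.20, other=0.20, condition="low",
                 aa=None, solutes=None, poly=23.04):
    aa = aa or {a: 1 / 20 for a in AMINO_ACIDS}
    return BiomassComposition(
        condition=condition,
        mass_fractions={"protein": protein, "dna": dna, "rna": rna, "other": other},
        amino_acid_ratios=aa,
        dnt_ratios=dnt_ratios_from_gc(0.64),
        nt_ratios={"ATP": 0.26, "CTP": 0.23, "GTP": 0.32, "UTP": 0.19},
        solute_coefficients=solutes or {},
        polymerization_cost=poly,
    )


_WEIGHTS = {a: 0.110 for a in AMINO_ACIDS}  # g mmol^-1, mean-residue scale
_WEIGHTS.update({"dATP": 0.491, "dCTP": 0.467, "dGTP": 0.507, "dTTP": 0.482})
_WEIGHTS.update({"ATP": 0.507, "CTP": 0.483, "GTP": 0.523, "UTP": 0.484})
_WEIGHTS.update({"ectoine": 0.1422, "hydroxyectoine": 0.1582})

_IDS = {a: f"{a.lower()}aa[c]" for a in AMINO_ACIDS}
_IDS.update({k: f"{k.lower()}[c]" for k in ("dATP", "dCTP", "dGTP", "dTTP",
                                            "ATP", "CTP", "GTP", "UTP")})
_IDS.update({"ectoine": "ect[c]", "hydroxyectoine": "hect[c]"})


class TestAssembleBiomass:
    def test_zero_protein_fraction_drops_amino_acids(self):
        comp = _composition(protein=0.0, other=0.75)
        rxn = assemble_biomass_reaction(comp, _WEIGHTS, _IDS)
        assert not any(mid.endswith("aa[c]") for mid in rxn.stoichiometry)

    def test_single_amino_acid_closed_form(self):
        aa = {a: 0.0 for a in AMINO_ACIDS}
        aa["G"] = 1.0
        comp = _composition(protein=0.5, dna=0.0, rna=0.0, other=0.5, aa=aa)
        w = 0.075
        weights = dict(_WEIGHTS, G=w)
        rxn = assemble_biomass_reaction(comp, weights, _IDS)
        assert rxn.stoichiometry[_IDS["G"]] == pytest.approx(-0.5 / w)

    def test_gam_term_differs_by_14_25_between_conditions(self):
        low = _composition(poly=23.04, condition="low")
        high = _composition(poly=8.79, condition="high")
        r_low = assemble_biomass_reaction(low, _WEIGHTS, _IDS)
        r_high = assemble_biomass_reaction(high, _WEIGHTS, _IDS)
        assert r_low.id == "BIO_L" and r_high.id == "BIO_H"
        # ATP consumption is GAM plus the RNA-precursor ATP drain (same in both)
        diff = r_high.stoichiometry["atp[c]"] - r_low.stoichiometry["atp[c]"]
        assert diff == pytest.approx(59.98 - 45.73, abs=1e-9)
        assert diff == pytest.approx(14.25, abs=1e-9)

    def test_mass_reconstruction_per_group(self):
        """sum |coeff| * monomer weight recovers each group's mass fraction."""
        comp = _composition(solutes={"ectoine": 0.35, "hydroxyectoine": 0.1})
        rxn = assemble_biomass_reaction(comp, _WEIGHTS, _IDS)
        protein_mass = sum(
            -rxn.stoichiometry[_IDS[a]] * _WEIGHTS[a]
            for a in AMINO_ACIDS
            if _IDS[a] in rxn.stoichiometry
        )
        assert protein_mass == pytest.approx(comp.mass_fractions["protein"], abs=1e-6)
        dna_mass = sum(
            -rxn.stoichiometry[_IDS[k]] * _WEIGHTS[k]
            for k in ("dATP", "dCTP", "dGTP", "dTTP")
        )
        assert dna_mass == pytest.approx(comp.mass_fractions["dna"], abs=1e-6)

    def test_energy_term_membership_invariant_across_conditions(self):
        low = _composition(poly=23.04, condition="low",
                           solutes={"ectoine": 0.05})
        high = _composition(poly=8.79, condition="high",
                            solutes={"ectoine": 0.45})
        r_low = assemble_biomass_reaction(low, _WEIGHTS, _IDS)
        r_high = assemble_biomass_reaction(high, _WEIGHTS, _IDS)
        for mid in ENERGY_TERM:
            assert mid in r_low.stoichiometry and mid in r_high.stoichiometry
        assert set(r_low.stoichiometry) == set(r_high.stoichiometry)

    def test_solute_coefficients_enter_directly(self):
        comp = _composition(solutes={"ectoine": 0.35})
        rxn = assemble_biomass_reaction(comp, _WEIGHTS, _IDS)
        assert rxn.stoichiometry["ect[c]"] == pytest.approx(-0.35)

    def test_missing_weight_names_monomer(self):
        weights = {k: v for k, v in _WEIGHTS.items() if k != "dGTP"}
        with pytest.raises(CompositionError, match="dGTP"):
            assemble_biomass_reaction(_composition(), weights, _IDS)

    def test_ratio_sum_invariant_enforced(self):
        bad = _composition()
        bad.amino_acid_ratios = {a: 0.06 for a in AMINO_ACIDS}  # sums to 1.2
        with pytest.raises(CompositionError, match="amino-acid"):
            bad.validate()
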